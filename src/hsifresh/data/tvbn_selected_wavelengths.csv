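wavelength_nm
428
430
450
457
476
481
492
505
506
510
511
515
516
517
521
522
528
541
543
553
587
594
600
639
653
656
673
685
692
707
710
759
777
784
811
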