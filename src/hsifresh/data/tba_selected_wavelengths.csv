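wavelength_nm
430
431
458
461
522
573
608
610
627
660
668
747
756
766
784
836
837
901
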