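# Molar extinction coefficients of human oxy- and deoxy-haemoglobin (cm^-1 M^-1)
# in the near-infrared window, after the standard compiled spectra used in
# photoacoustic oximetry. Version: 1.0
wavelength_nm,eps_hb_oxy,eps_hb_deoxy
750,518.0,1405.24
760,586.0,1548.52
780,710.0,1075.44
800,816.0,761.72
830,974.0,693.04
850,1058.0,691.32
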