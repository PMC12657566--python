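# Molar extinction coefficients of hemoglobin, base-10 convention,
# units cm^-1 M^-1, i.e. A = epsilon * c * L with c in mol/L and L in cm.
# Source: S. Prahl, "Optical absorption of hemoglobin", Oregon Medical
# Laser Center compilation (https://omlc.org/spectra/hemoglobin/), which
# merges the tabulations of W. B. Gratzer and N. Kollias.
wavelength_nm,hbo,hbr
690,276.0,2051.96
730,390.0,1102.2
760,586.0,1548.52
780,710.0,1075.44
808,844.0,723.52
830,974.0,693.04
850,1058.0,691.32
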