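# Default NIR band library for the synthetic soy spectra generator.
#
# Each component is a list of Gaussian bands {center_nm, sigma_nm, height}
# where height is apparent absorbance contributed per unit mass fraction of
# the component. Centers sit on published soy band assignments: protein
# N-H/C=O combination bands at 2063 and 2188 nm; fatty-acid C-H first
# overtones in the 1695-1786 nm window (oleate near 1709 nm,
# polyunsaturates near 1731 nm); water O-H at ~1450 and ~1940 nm;
# carbohydrate C-H combination bands at 2100, 2273 and 2480 nm.
# Heights are a one-time tuning: the fat first-overtone bands are given
# deliberately large heights so that, at the generator's default noise
# level, the high-oleic vs conventional class contrast in the 1695-1786 nm
# window dominates within-class variation (exaggerated relative to real
# ground-soybean spectra, where the fat overtone is a modest shoulder).
components:
  protein:
    - {center_nm: 2063.0, sigma_nm: 35.0, height: 0.88}
    - {center_nm: 2188.0, sigma_nm: 30.0, height: 0.64}
    - {center_nm: 2285.0, sigma_nm: 40.0, height: 0.28}
  fat_oleic:
    - {center_nm: 1709.0, sigma_nm: 16.0, height: 12.0}
    - {center_nm: 1762.0, sigma_nm: 22.0, height: 4.0}
    - {center_nm: 2310.0, sigma_nm: 24.0, height: 4.8}
  fat_linoleic_linolenic:
    - {center_nm: 1731.0, sigma_nm: 16.0, height: 12.0}
    - {center_nm: 1772.0, sigma_nm: 22.0, height: 4.0}
    - {center_nm: 2310.0, sigma_nm: 24.0, height: 4.4}
  fat_saturated:
    - {center_nm: 1724.0, sigma_nm: 20.0, height: 8.8}
    - {center_nm: 2306.0, sigma_nm: 24.0, height: 4.0}
  water:
    - {center_nm: 1450.0, sigma_nm: 28.0, height: 0.80}
    - {center_nm: 1940.0, sigma_nm: 32.0, height: 1.04}
  carbohydrate:
    - {center_nm: 2100.0, sigma_nm: 42.0, height: 0.48}
    - {center_nm: 2273.0, sigma_nm: 34.0, height: 0.36}
    - {center_nm: 2480.0, sigma_nm: 30.0, height: 0.32}
    - {center_nm: 1585.0, sigma_nm: 60.0, height: 0.14}
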