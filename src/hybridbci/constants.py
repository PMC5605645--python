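"""Physical constants and pipeline defaults.

Every fixed number the pipeline relies on lives here so it can be audited
in one place.
"""

import numpy as np

#: wavelengths of the two optical channels (nm)
WAVELENGTHS_NM = (760, 850)

#: differential path-length factors per wavelength
DPF_760 = 7.15
DPF_850 = 6.38

#: molar (base-10) extinction coefficients, cm^-1 / (mol/L).
#: Rows: wavelength (760, 850 nm); columns: (HbO, HbR).
#: Standard hemoglobin tabulation as distributed with common NIRS toolboxes.
EXTINCTION = np.array([
    [586.0, 1548.52],   # 760 nm
    [1058.0, 691.32],   # 850 nm
])

MICROMOLAR_TO_MOLAR = 1e-6

# --- preprocessing defaults -------------------------------------------------
EEG_FS_OUT = 250.0
EEG_BAND_HZ = (1.0, 45.0)
EEG_FILTER_ORDER = 3
FNIRS_BAND_HZ = (0.01, 0.2)
FNIRS_FILTER_ORDER = 4

EEG_EPOCH_WINDOW_S = (-2.0, 5.0)
EEG_BASELINE_WINDOW_S = (-2.0, 0.0)
FNIRS_EPOCH_WINDOW_S = (-5.0, 20.0)
FNIRS_BASELINE_WINDOW_S = (-5.0, 0.0)

MOTION_STD_WINDOW_S = 1.0
MOTION_STD_K = 3.0

#: seconds of the recording start used as the optical-intensity reference
MBLL_REFERENCE_S = 5.0

# --- feature defaults -------------------------------------------------------
EEG_FEATURE_WINDOW_S = (0.0, 1.0)
DIP_FEATURE_WINDOW_S = (0.0, 2.0)
DWT_LEVELS = 4
DWT_WAVELET = "sym4"
PCA_COMPONENTS = 1

# --- classifier defaults ----------------------------------------------------
SVM_C = 1.0
GLM_ALPHA = 0.05
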