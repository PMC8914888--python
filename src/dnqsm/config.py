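"""Physical constants and acquisition defaults.

All frequency/field conversions in the package go through the constants
defined here; operations never hard-code them.
"""

#: Gyromagnetic ratio of the proton, MHz per tesla.
GAMMA_MHZ_PER_T = 42.576

#: Main field strength of the acquisition, tesla.
B0_TESLA = 3.0

#: Larmor frequency at 3 T, Hz (B0 × γ).
F0_HZ = B0_TESLA * GAMMA_MHZ_PER_T * 1e6  # 127.728 MHz

#: Echo times of the four-echo gradient-echo protocol, seconds.
DEFAULT_TES_S = (0.00647, 0.01723, 0.02799, 0.03875)

#: Isotropic voxel size of the susceptibility acquisition, mm.
DEFAULT_VOXEL_SIZE_MM = 0.5

#: R2* (s^-1) below which a voxel is treated as CSF and excluded from DN_bulk.
R2STAR_CSF_THRESHOLD_S = 15.0

#: Default significance level for group statistics.
DEFAULT_ALPHA = 0.05
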