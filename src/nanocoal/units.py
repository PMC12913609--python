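"""Exact unit-conversion factors between SI and the lab units used at I/O.

Everything inside the library is SI (m, s, kg/m**3, Pa*s, K).  User-facing
interfaces speak nm, ms, g/L, mPa*s and g/cm**3; the factors below are exact
by definition of the units.
"""

NM_PER_M = 1e9
M_PER_NM = 1e-9

MS_PER_S = 1e3
S_PER_MS = 1e-3

# 1 g/L == 1 kg/m**3 exactly.
KG_M3_PER_G_L = 1.0
G_L_PER_KG_M3 = 1.0

PA_S_PER_MPA_S = 1e-3
MPA_S_PER_PA_S = 1e3

KG_M3_PER_G_CM3 = 1e3


def nm_to_m(x: float) -> float:
    return x * M_PER_NM


def m_to_nm(x: float) -> float:
    return x * NM_PER_M


def ms_to_s(x: float) -> float:
    return x * S_PER_MS


def s_to_ms(x: float) -> float:
    return x * MS_PER_S


def mpa_s_to_pa_s(x: float) -> float:
    return x * PA_S_PER_MPA_S


def g_cm3_to_kg_m3(x: float) -> float:
    return x * KG_M3_PER_G_CM3
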