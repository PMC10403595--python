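"""Unit conversions. Internals are CGS; conversions apply only in reports."""

DYN_PER_CM2_PER_MMHG = 1333.22      # 1 mmHg in dyn/cm^2
ERG_PER_S_PER_MW = 1.0e4            # 1 mW in erg/s
CM3_PER_S_PER_L_PER_MIN = 1000.0 / 60.0


def dyncm2_to_mmhg(p: float) -> float:
    return p / DYN_PER_CM2_PER_MMHG


def ergs_to_mw(e: float) -> float:
    return e / ERG_PER_S_PER_MW


def lmin_to_cm3s(q: float) -> float:
    return q * CM3_PER_S_PER_L_PER_MIN
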