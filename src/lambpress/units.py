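"""Unit conversions. SI internally; mmHg and ml only at I/O boundaries."""

MMHG = 133.322387415  # Pa per mmHg
ML = 1e-6  # m^3 per millilitre


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG


def ml_to_m3(v_ml: float) -> float:
    return v_ml * ML


def m3_to_ml(v_m3: float) -> float:
    return v_m3 / ML
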