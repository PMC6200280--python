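"""Independent transcription of the model equations, used as an oracle.

This module re-derives the 20 time derivatives directly from the printed
equation list, organized completely differently from the packaged kernel
(dict-based, one expression per species, no shared flux variables), so
that agreement between the two is a meaningful check of the
transcription rather than of a single shared implementation.
"""

from __future__ import annotations

import numpy as np


def reference_rhs(s: dict, q: dict, k: dict) -> dict:
    """Derivatives (nM/s) from a per-equation transcription.

    ``s``: species concentrations; ``q``: total pools; ``k``: rate
    constants. All states must be non-negative and within pool bounds.
    """
    lck_active = s["lck_yiya"] + s["lck_ya"]
    cp = s["cp1"] + s["cp2"]
    free_cd3 = q["cd3T"] - (s["cd3a"] + s["zap70i"] + s["zap70a1"] + s["zap70a2"])
    free_zap = q["zap70T"] - (s["zap70i"] + s["zap70a1"] + s["zap70a2"])
    free_cd28 = q["cd28T"] - (s["cd28a"] + s["pi3kb"])
    free_pi3k = q["pi3kT"] - s["pi3kb"]
    lck_i = q["lckT"] - (s["lck_yiya"] + s["lck_yi"] + s["lck_ya"] + s["lck_pi"])
    free_lat = q["latT"] - (s["lata"] + s["gadsa"] + s["slp76i"] + s["slp76a"])
    free_gads = q["gadsT"] - (s["gadsa"] + s["slp76a"] + s["slp76i"])
    free_slp = q["slp76T"] - (s["slp76i"] + s["slp76a"])

    if q["lckT"] > 0:
        corr = max(0.0, 1.0 - (s["pd1p1"] + s["pd1p2"]) / (q["lckT"] * k["k_corr"]))
    else:
        corr = 1.0

    d = {}
    d["cd3a"] = (
        k["k_p_cd3"] * lck_active * free_cd3 / (k["KM_p_cd3"] + free_cd3)
        - k["k_dp_cd3"] * cp * s["cd3a"] / (k["KM_dp_cd3"] + s["cd3a"])
        + k["k_d_zap"] * s["zap70i"]
        - k["k_a_zap"] * s["cd3a"] * free_zap
    )
    d["cd28a"] = (
        k["k_p_cd28"] * lck_active * free_cd28 / (k["KM_p_cd28"] + free_cd28)
        - k["k_dp_cd28"] * cp * s["cd28a"] / (k["KM_dp_cd28"] + s["cd28a"])
        + k["k_d_pi3k"] * s["pi3kb"]
        - k["k_a_pi3k"] * s["cd28a"] * free_pi3k
    )
    d["pd1p1"] = (
        k["k_p_pd1"] * lck_active * s["pd1"] / (k["KM_p_pd1"] + s["pd1"]) * corr
        - k["k_p_pd1"] * s["pd1p1"] * lck_active / (k["KM_p_pd1"] + s["pd1p1"])
        - k["k_a_shp"] * s["pd1p1"] * s["shp2_free"]
        + k["k_d1_shp"] * s["cp1"]
        + k["k_d2_shp"] * s["cp2"]
    )
    d["pd1"] = (
        -k["k_p_pd1"] * lck_active * s["pd1"] / (k["KM_p_pd1"] + s["pd1"]) * corr
        + k["k_d2_shp"] * s["cp1"]
    )
    d["pd1p2"] = (
        k["k_p_pd1"] * s["pd1p1"] * lck_active / (k["KM_p_pd1"] + s["pd1p1"])
        - k["k_a_shp"] * s["pd1p2"] * s["shp2_free"]
        + k["k_d1_shp"] * s["cp2"]
    )
    d["shp2_free"] = (
        -k["k_a_shp"] * s["shp2_free"] * (s["pd1p1"] + s["pd1p2"])
        + k["k_d1_shp"] * (s["cp1"] + s["cp2"])
        + k["k_d2_shp"] * (s["cp1"] + s["cp2"])
    )
    d["cp1"] = (
        k["k_dp_cp2"] * s["cp2"]
        + k["k_a_shp"] * s["pd1p1"] * s["shp2_free"]
        - k["k_d1_shp"] * s["cp1"]
        - k["k_d2_shp"] * s["cp1"]
    )
    d["cp2"] = (
        -k["k_dp_cp2"] * s["cp2"]
        + k["k_a_shp"] * s["pd1p2"] * s["shp2_free"]
        - k["k_d1_shp"] * s["cp2"]
        - k["k_d2_shp"] * s["cp2"]
    )
    d["lck_yiya"] = (
        -k["k_dpa_yiya"] * cp * s["lck_yiya"]
        - k["k_dpi_yiya"] * cp * s["lck_yiya"]
        + k["k_pi_ya"] * s["lck_ya"]
    )
    d["lck_yi"] = (
        k["k_dpa_yiya"] * cp * s["lck_yiya"]
        - k["k_dpi_yi"] * cp * s["lck_yi"]
        + k["k_pi_i"] * lck_i
        - k["k_pa_yi"] * s["lck_yi"]
        + k["k_dpa_pi"] * cp * s["lck_pi"]
    )
    d["lck_ya"] = (
        k["k_dpi_yiya"] * cp * s["lck_yiya"]
        - k["k_pi_ya"] * s["lck_ya"]
        - k["k_dpa_ya"] * cp * s["lck_ya"]
        + k["k_pa_i"] * lck_i
    )
    d["lck_pi"] = -k["k_dpa_pi"] * cp * s["lck_pi"] + k["k_pa_yi"] * s["lck_yi"]
    d["zap70i"] = (
        k["k_a_zap"] * s["cd3a"] * free_zap
        - k["k_d_zap"] * s["zap70i"]
        - k["k_p1_zap"] * lck_active * s["zap70i"]
    )
    d["zap70a1"] = (
        k["k_p1_zap"] * lck_active * s["zap70i"]
        - k["k_p2_zap"] * lck_active * s["zap70a1"]
    )
    d["zap70a2"] = k["k_p2_zap"] * lck_active * s["zap70a1"]
    d["lata"] = (
        k["k_p_lat"] * s["zap70a2"] * free_lat
        - k["k_a_gads"] * s["lata"] * free_gads
        + k["k_d_gads"] * s["gadsa"]
    )
    d["slp76i"] = (
        k["k_a_slp"] * s["gadsa"] * free_slp
        - k["k_d_slp"] * s["slp76i"]
        - k["k_p_slp"] * s["slp76i"] * s["zap70a2"]
    )
    d["slp76a"] = k["k_p_slp"] * s["slp76i"] * s["zap70a2"]
    d["gadsa"] = (
        k["k_a_gads"] * s["lata"] * free_gads
        - k["k_d_gads"] * s["gadsa"]
        - k["k_a_slp"] * s["gadsa"] * free_slp
        + k["k_d_slp"] * s["slp76i"]
    )
    d["pi3kb"] = k["k_a_pi3k"] * s["cd28a"] * free_pi3k - k["k_d_pi3k"] * s["pi3kb"]
    return d


def random_valid_state(rng: np.random.Generator) -> tuple[dict, dict]:
    """Draw pools and a species state satisfying every pool bound."""
    q = {name: float(rng.uniform(50.0, 500.0)) for name in (
        "cd3T", "cd28T", "zap70T", "pi3kT", "lckT",
        "latT", "gadsT", "slp76T", "shp2T", "pd1T",
    )}
    s = {}
    # Zap70 ladder occupies both CD3zeta and Zap70 pools.
    zap_budget = 0.9 * min(q["zap70T"], q["cd3T"])
    z = rng.random(3)
    z = z / z.sum() * float(rng.uniform(0, zap_budget))
    s["zap70i"], s["zap70a1"], s["zap70a2"] = map(float, z)
    s["cd3a"] = float(rng.uniform(0, q["cd3T"] - z.sum()))
    # CD28 / PI3K.
    s["pi3kb"] = float(rng.uniform(0, 0.9 * min(q["pi3kT"], q["cd28T"])))
    s["cd28a"] = float(rng.uniform(0, q["cd28T"] - s["pi3kb"]))
    # Lck phosphoforms.
    l = rng.random(4)
    l = l / l.sum() * float(rng.uniform(0, q["lckT"]))
    s["lck_yiya"], s["lck_yi"], s["lck_ya"], s["lck_pi"] = map(float, l)
    # LAT / Gads / Slp76 chain.
    slp_budget = 0.9 * min(q["slp76T"], q["gadsT"], q["latT"])
    w = rng.random(2)
    w = w / w.sum() * float(rng.uniform(0, slp_budget))
    s["slp76i"], s["slp76a"] = map(float, w)
    s["gadsa"] = float(rng.uniform(0, min(q["gadsT"], q["latT"]) - w.sum()))
    s["lata"] = float(rng.uniform(0, q["latT"] - w.sum() - s["gadsa"]))
    # PD-1 family and Shp2 (conserved totals follow from the draw).
    pd1_parts = rng.random(5)
    pd1_parts = pd1_parts / pd1_parts.sum() * q["pd1T"]
    s["pd1"], s["pd1p1"], s["pd1p2"], s["cp1"], s["cp2"] = map(float, pd1_parts)
    s["shp2_free"] = float(rng.uniform(0.0, 300.0))
    q["shp2T"] = s["shp2_free"] + s["cp1"] + s["cp2"]
    return s, q
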