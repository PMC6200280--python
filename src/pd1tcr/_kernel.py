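"""Compiled right-hand side of the 20-species signaling ODE system.

The kernel is written against flat float64 vectors so that it can be
jit-compiled with numba and called tightly from the stiff integrator.
State, pool and parameter orderings are defined in :mod:`pd1tcr.model`
and :mod:`pd1tcr.parameters`; this module must be kept in lock-step with
those orderings.

Free (unbound, unphosphorylated) pools are never integrated: they are
eliminated algebraically through the conservation relations at every
evaluation, which makes the corresponding totals conserved exactly.
"""

import numpy as np
from numba import njit

# State indices (canonical species order).
I_CD3A = 0
I_CD28A = 1
I_PD1 = 2
I_PD1P1 = 3
I_PD1P2 = 4
I_SHP2 = 5
I_CP1 = 6
I_CP2 = 7
I_LCK_YIYA = 8
I_LCK_YI = 9
I_LCK_YA = 10
I_LCK_PI = 11
I_ZAP70I = 12
I_ZAP70A1 = 13
I_ZAP70A2 = 14
I_LATA = 15
I_SLP76I = 16
I_SLP76A = 17
I_GADSA = 18
I_PI3KB = 19

N_SPECIES = 20

# Pool indices.
J_CD3T = 0
J_CD28T = 1
J_ZAP70T = 2
J_PI3KT = 3
J_LCKT = 4
J_LATT = 5
J_GADST = 6
J_SLP76T = 7
J_SHP2T = 8
J_PD1T = 9

N_POOLS = 10

# Parameter indices (canonical parameter order of pd1tcr.parameters).
P_K_DPA_YIYA = 0
P_K_DPI_YI = 1
P_K_DPI_YIYA = 2
P_K_DPA_YA = 3
P_K_DPA_PI = 4
P_K_A_ZAP = 5
P_K_P1_ZAP = 6
P_K_P2_ZAP = 7
P_K_P_LAT = 8
P_K_A_SLP = 9
P_K_P_SLP = 10
P_K_A_GADS = 11
P_K_A_PI3K = 12
P_K_A_SHP = 13
P_K_PI_I = 14
P_K_PI_YA = 15
P_K_PA_I = 16
P_K_PA_YI = 17
P_K_P_CD3 = 18
P_K_DP_CD3 = 19
P_K_D_ZAP = 20
P_K_D_SLP = 21
P_K_D_GADS = 22
P_K_P_CD28 = 23
P_K_DP_CD28 = 24
P_K_D_PI3K = 25
P_K_P_PD1 = 26
P_K_D1_SHP = 27
P_K_DP_CP2 = 28
P_K_D2_SHP = 29
P_KM_P_CD3 = 30
P_KM_DP_CD3 = 31
P_KM_P_CD28 = 32
P_KM_DP_CD28 = 33
P_KM_P_PD1 = 34
P_K_CORR = 35

N_PARAMS = 36


@njit(cache=True)
def rhs_kernel(y, pools, p, clamp_cp2, clamp_value, out):  # pragma: no cover - exercised via model.rhs
    """Time derivatives (nM/s) of the 20 integrated species.

    ``clamp_cp2`` freezes the CP2 complex at ``clamp_value``: its time
    derivative is zero and every flux that would form or consume CP2
    (Shp2 binding to doubly phosphorylated PD-1, dissociation, and
    self-dephosphorylation of CP2) is disabled, while its catalytic
    activity is retained. This represents an experimentally tethered,
    non-exchanging membrane pool of Shp2.
    """
    # Clip integrator undershoot so that fluxes stay physical.
    s = np.empty(N_SPECIES)
    for i in range(N_SPECIES):
        v = y[i]
        s[i] = v if v > 0.0 else 0.0

    cd3a = s[I_CD3A]
    cd28a = s[I_CD28A]
    pd1 = s[I_PD1]
    pd1p1 = s[I_PD1P1]
    pd1p2 = s[I_PD1P2]
    shp2 = s[I_SHP2]
    cp1 = s[I_CP1]
    cp2 = clamp_value if clamp_cp2 else s[I_CP2]
    lck_yiya = s[I_LCK_YIYA]
    lck_yi = s[I_LCK_YI]
    lck_ya = s[I_LCK_YA]
    lck_pi = s[I_LCK_PI]
    zap70i = s[I_ZAP70I]
    zap70a1 = s[I_ZAP70A1]
    zap70a2 = s[I_ZAP70A2]
    lata = s[I_LATA]
    slp76i = s[I_SLP76I]
    slp76a = s[I_SLP76A]
    gadsa = s[I_GADSA]
    pi3kb = s[I_PI3KB]

    lck_active = lck_yiya + lck_ya
    cp_active = cp1 + cp2

    # Free pools by conservation.
    free_cd3 = pools[J_CD3T] - (cd3a + zap70i + zap70a1 + zap70a2)
    free_cd28 = pools[J_CD28T] - (cd28a + pi3kb)
    free_zap = pools[J_ZAP70T] - (zap70i + zap70a1 + zap70a2)
    free_pi3k = pools[J_PI3KT] - pi3kb
    free_lck_i = pools[J_LCKT] - (lck_yiya + lck_yi + lck_ya + lck_pi)
    free_lat = pools[J_LATT] - (lata + gadsa + slp76i + slp76a)
    free_gads = pools[J_GADST] - (gadsa + slp76i + slp76a)
    free_slp = pools[J_SLP76T] - (slp76i + slp76a)
    if free_cd3 < 0.0:
        free_cd3 = 0.0
    if free_cd28 < 0.0:
        free_cd28 = 0.0
    if free_zap < 0.0:
        free_zap = 0.0
    if free_pi3k < 0.0:
        free_pi3k = 0.0
    if free_lck_i < 0.0:
        free_lck_i = 0.0
    if free_lat < 0.0:
        free_lat = 0.0
    if free_gads < 0.0:
        free_gads = 0.0
    if free_slp < 0.0:
        free_slp = 0.0

    # Saturation correction for the first PD-1 phosphorylation step.
    lckT = pools[J_LCKT]
    if lckT > 0.0:
        corr = 1.0 - (pd1p1 + pd1p2) / (lckT * p[P_K_CORR])
        if corr < 0.0:
            corr = 0.0
    else:
        corr = 1.0  # lck_active is necessarily 0; the flux vanishes anyway

    # Michaelis-Menten fluxes on receptors.
    f_p_cd3 = p[P_K_P_CD3] * lck_active * free_cd3 / (p[P_KM_P_CD3] + free_cd3)
    f_dp_cd3 = p[P_K_DP_CD3] * cp_active * cd3a / (p[P_KM_DP_CD3] + cd3a)
    f_p_cd28 = p[P_K_P_CD28] * lck_active * free_cd28 / (p[P_KM_P_CD28] + free_cd28)
    f_dp_cd28 = p[P_K_DP_CD28] * cp_active * cd28a / (p[P_KM_DP_CD28] + cd28a)
    f_p_pd1 = p[P_K_P_PD1] * lck_active * pd1 / (p[P_KM_P_PD1] + pd1) * corr
    f_p_pd1p1 = p[P_K_P_PD1] * lck_active * pd1p1 / (p[P_KM_P_PD1] + pd1p1)

    # Shp2 binding / release.
    f_a_cp1 = p[P_K_A_SHP] * pd1p1 * shp2
    f_a_cp2 = p[P_K_A_SHP] * pd1p2 * shp2
    f_d1_cp1 = p[P_K_D1_SHP] * cp1
    f_d1_cp2 = p[P_K_D1_SHP] * cp2
    f_d2_cp1 = p[P_K_D2_SHP] * cp1
    f_d2_cp2 = p[P_K_D2_SHP] * cp2
    f_dp_cp2 = p[P_K_DP_CP2] * cp2
    if clamp_cp2:
        f_a_cp2 = 0.0
        f_d1_cp2 = 0.0
        f_d2_cp2 = 0.0
        f_dp_cp2 = 0.0

    out[I_CD3A] = f_p_cd3 - f_dp_cd3 + p[P_K_D_ZAP] * zap70i - p[P_K_A_ZAP] * cd3a * free_zap
    out[I_CD28A] = (
        f_p_cd28 - f_dp_cd28 + p[P_K_D_PI3K] * pi3kb - p[P_K_A_PI3K] * cd28a * free_pi3k
    )
    out[I_PD1P1] = f_p_pd1 - f_p_pd1p1 - f_a_cp1 + f_d1_cp1 + f_d2_cp2
    out[I_PD1] = -f_p_pd1 + f_d2_cp1
    out[I_PD1P2] = f_p_pd1p1 - f_a_cp2 + f_d1_cp2
    out[I_SHP2] = -(f_a_cp1 + f_a_cp2) + (f_d1_cp1 + f_d1_cp2) + (f_d2_cp1 + f_d2_cp2)
    out[I_CP1] = f_dp_cp2 + f_a_cp1 - f_d1_cp1 - f_d2_cp1
    out[I_CP2] = 0.0 if clamp_cp2 else (-f_dp_cp2 + f_a_cp2 - f_d1_cp2 - f_d2_cp2)

    out[I_LCK_YIYA] = (
        -p[P_K_DPA_YIYA] * cp_active * lck_yiya
        - p[P_K_DPI_YIYA] * cp_active * lck_yiya
        + p[P_K_PI_YA] * lck_ya
    )
    out[I_LCK_YI] = (
        p[P_K_DPA_YIYA] * cp_active * lck_yiya
        - p[P_K_DPI_YI] * cp_active * lck_yi
        + p[P_K_PI_I] * free_lck_i
        - p[P_K_PA_YI] * lck_yi
        + p[P_K_DPA_PI] * cp_active * lck_pi
    )
    out[I_LCK_YA] = (
        p[P_K_DPI_YIYA] * cp_active * lck_yiya
        - p[P_K_PI_YA] * lck_ya
        - p[P_K_DPA_YA] * cp_active * lck_ya
        + p[P_K_PA_I] * free_lck_i
    )
    out[I_LCK_PI] = -p[P_K_DPA_PI] * cp_active * lck_pi + p[P_K_PA_YI] * lck_yi

    out[I_ZAP70I] = (
        p[P_K_A_ZAP] * cd3a * free_zap
        - p[P_K_D_ZAP] * zap70i
        - p[P_K_P1_ZAP] * lck_active * zap70i
    )
    out[I_ZAP70A1] = (
        p[P_K_P1_ZAP] * lck_active * zap70i - p[P_K_P2_ZAP] * lck_active * zap70a1
    )
    out[I_ZAP70A2] = p[P_K_P2_ZAP] * lck_active * zap70a1

    out[I_LATA] = (
        p[P_K_P_LAT] * zap70a2 * free_lat
        - p[P_K_A_GADS] * lata * free_gads
        + p[P_K_D_GADS] * gadsa
    )
    out[I_SLP76I] = (
        p[P_K_A_SLP] * gadsa * free_slp
        - p[P_K_D_SLP] * slp76i
        - p[P_K_P_SLP] * slp76i * zap70a2
    )
    out[I_SLP76A] = p[P_K_P_SLP] * slp76i * zap70a2
    out[I_GADSA] = (
        p[P_K_A_GADS] * lata * free_gads
        - p[P_K_D_GADS] * gadsa
        - p[P_K_A_SLP] * gadsa * free_slp
        + p[P_K_D_SLP] * slp76i
    )
    out[I_PI3KB] = p[P_K_A_PI3K] * cd28a * free_pi3k - p[P_K_D_PI3K] * pi3kb
    return out
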