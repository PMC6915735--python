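"""Deliberately naive, loop-per-day reference implementation of the crop
water-balance model, transcribed straight from the documented daily update
order.  Used only as an independent cross-check of the production engine's
trace; keep it free of any import from the engine's internals.
"""

import math


def naive_season_trace(
    n_days,
    tmin,
    tmax,
    precip,
    et0,
    *,
    # soil
    theta_fc=0.32,
    theta_wp=0.17,
    ksat=100.0,
    initial_depletion_fraction=0.5,
    min_root_depth=0.3,
    max_root_depth=1.0,
    rew=9.0,
    evap_layer_depth=0.1,
    # crop
    cc0=0.03,
    ccx=0.96,
    cgc=0.008,
    cdc=0.002,
    kc_tr_x=1.1,
    ke_max=1.1,
    wp_star=15.0,
    hi0=0.48,
    p_expansion=0.2,
    p_stomata=0.65,
    shape=3.0,
    tbase=0.0,
    tupper=26.0,
    gdd_emergence=40.0,
    gdd_max_canopy=200.0,
    gdd_senescence=400.0,
    gdd_maturity=600.0,
    gdd_flowering=None,
    f_co2=1.0,
    irrigate=True,
    trigger=0.5,
):
    """Return a list of per-day dicts with the bucket-model trace."""

    def ks(dr, taw, p):
        if taw <= 0:
            raise ValueError("taw must be positive")
        d = min(max(dr, 0.0), taw)
        thresh = p * taw
        if d <= thresh:
            return 1.0
        s = (d - thresh) / (taw - thresh)
        if shape == 0.0:
            return 1.0 - s
        return 1.0 - math.expm1(s * shape) / math.expm1(shape)

    if gdd_flowering is None:
        gdd_flowering = 0.5 * (gdd_max_canopy + gdd_senescence)
    tew = 1000.0 * (theta_fc - 0.5 * theta_wp) * evap_layer_depth
    dr = initial_depletion_fraction * (1000.0 * (theta_fc - theta_wp) * min_root_depth)
    de = min(dr, tew)
    cc = 0.0
    cum_gdd = 0.0
    biomass = 0.0
    hi = 0.0
    flowering = False
    hi_span = gdd_maturity - gdd_flowering
    root_span = max_root_depth - min_root_depth
    gdd_span = gdd_max_canopy - gdd_emergence

    rows = []
    for i in range(n_days):
        # 1. thermal time
        tavg = (tmin[i] + tmax[i]) / 2.0
        gdd_today = min(max(tavg, tbase), tupper) - tbase
        cum_gdd += gdd_today

        # 2. root zone
        frac = (cum_gdd - gdd_emergence) / gdd_span if gdd_span > 0 else 1.0
        frac = min(max(frac, 0.0), 1.0)
        z = min_root_depth + root_span * frac
        taw = 1000.0 * (theta_fc - theta_wp) * z
        if dr > taw:
            dr = taw

        # 3. irrigation decision
        irr = dr if (irrigate and dr > trigger * taw) else 0.0

        # 4. surface wetting
        dr_start = dr
        de = max(0.0, de - precip[i] - irr)

        # 5. canopy development
        ks_exp = ks(max(dr - precip[i] - irr, 0.0), taw, p_expansion)
        if cum_gdd < gdd_emergence:
            cc = 0.0
        elif cum_gdd < gdd_senescence:
            if cc <= 0.0:
                cc = cc0
            growth = cgc * ks_exp * gdd_today
            if cc <= ccx / 2.0:
                cc = cc * math.exp(growth)
            else:
                cc = ccx - (ccx - cc) * math.exp(-growth)
            cc = min(cc, ccx)
        else:
            cc = max(0.0, cc - cdc * gdd_today)

        # 6.-7. evapotranspiration partition
        cc_star = 1.72 * cc - cc * cc + 0.30 * cc * cc * cc
        ks_sto = ks(max(dr - precip[i] - irr, 0.0), taw, p_stomata)
        if de <= rew:
            kr = 1.0
        elif de >= tew:
            kr = 0.0
        else:
            kr = (tew - de) / (tew - rew)
        tr = ks_sto * kc_tr_x * cc_star * et0[i]
        e = kr * ke_max * (1.0 - min(cc_star, 1.0)) * et0[i]

        # 8. bucket update with supply cap
        dr1 = dr - precip[i] - irr
        drainage = 0.0
        if dr1 < 0.0:
            excess = -dr1
            drainage = excess if excess <= ksat else ksat
            dr1 = -(excess - drainage)
        available = taw - dr1
        demand = e + tr
        if demand > available:
            f = available / demand if demand > 0.0 else 0.0
            f = max(f, 0.0)
            e = e * f
            tr = tr * f
        dr = dr1 + e + tr
        de = min(tew, de + e)

        # 9. biomass and harvest index
        if tr != 0.0:
            biomass += wp_star * f_co2 * (tr / et0[i])
        if not flowering and cum_gdd >= gdd_flowering:
            flowering = True
        if flowering:
            hi = hi0 * min(1.0, (cum_gdd - gdd_flowering) / hi_span)

        rows.append(
            {
                "gdd": gdd_today,
                "cum_gdd": cum_gdd,
                "cc": cc,
                "root_depth": z,
                "taw": taw,
                "dr": dr,
                "de": de,
                "e": e,
                "tr": tr,
                "irrigation": irr,
                "precip": precip[i],
                "drainage": drainage,
                "biomass": biomass,
                "hi": hi,
                "ks_expansion": ks_exp,
                "ks_stomata": ks_sto,
            }
        )
        if cum_gdd >= gdd_maturity:
            break
    return rows
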