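"""Straight-line arithmetic oracles, written independently of the package.

Each function spells out one guideline formula as a single expression over
plain floats, so the engine can be checked against an implementation that
shares none of its code paths.
"""


def oral_cdi(cw, gwcr, ef, ed, bw, at):
    return cw * gwcr * ef * ed / (bw * at)


def dermal_dose(cw, kp, t_event, ev, sa, ef, ed, bw, at):
    return cw * kp * t_event * ev * sa * ef * ed * 1e-3 / (bw * at)


def effective_diffusion(d_air, d_water, henry, theta_a, theta_w, theta_t):
    return (
        d_air * theta_a**3.33 / theta_t**2
        + (d_water / henry) * theta_w**3.33 / theta_t**2
    )


def vf_outdoor(henry, d_eff, u_air, delta_air, l_gw, w):
    return 1000.0 * henry / (1.0 + u_air * delta_air * l_gw / (d_eff * w))


def vf_indoor(henry, d_eff, l_gw, er, lb, eta, l_crack):
    r = (d_eff / l_gw) / (er * lb)
    return 1000.0 * henry * r / (1.0 + r + (d_eff / l_gw) / (d_eff * eta / l_crack))


def inhalation_ec(cw, vf, et, ef, ed, at):
    return cw * vf * et * ef * ed / (24.0 * at)


def ingestion_cr(cw, gwcr, ef, ed, bw, at_c, sf):
    return oral_cdi(cw, gwcr, ef, ed, bw, at_c) * sf


def ingestion_hq(cw, gwcr, ef, ed, bw, at_nc, rfd):
    return oral_cdi(cw, gwcr, ef, ed, bw, at_nc) / rfd


def dermal_cr(cw, kp, t_event, ev, sa, ef, ed, bw, at_c, sf, abs_gi):
    return dermal_dose(cw, kp, t_event, ev, sa, ef, ed, bw, at_c) * sf / abs_gi


def dermal_hq(cw, kp, t_event, ev, sa, ef, ed, bw, at_nc, rfd, abs_gi):
    return dermal_dose(cw, kp, t_event, ev, sa, ef, ed, bw, at_nc) / (rfd * abs_gi)


def inhalation_cr(cw, vf, et, ef, ed, at_c, iur):
    return inhalation_ec(cw, vf, et, ef, ed, at_c) * 1000.0 * iur


def inhalation_hq(cw, vf, et, ef, ed, at_nc, rfc):
    return inhalation_ec(cw, vf, et, ef, ed, at_nc) / rfc
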