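"""Independent numeric oracles used to check the closed-form rate laws.

The oracles never call the package's rate functions: they enumerate the
enzyme species of the rapid-equilibrium scheme explicitly, compute each
complex's relative concentration from its binding path, normalize, and read
the flux off the catalytically competent ternary complex.
"""

import itertools


def species_fractions(species: dict) -> dict:
    total = sum(species.values())
    return {name: conc / total for name, conc in species.items()}


def branch_species(p: dict, a: float, b: float, products: float,
                   comp_conc: float = 0.0, comp_ki: float = None,
                   comp_km: float = None) -> dict:
    """Relative enzyme-species concentrations for one cofactor branch.

    p holds kcat, km_cofactor, ki_cofactor, km_g6p, kic_product and optional
    kis_cofactor.  A = G6P binds free enzyme with the box-closed constant
    kia = ki_cofactor*km_g6p/km_cofactor and the E.B complex with km_g6p;
    B binds free enzyme with ki_cofactor and E.A with km_cofactor; the
    branch's own reduced cofactor (``products``) binds E and E.A with
    kic_product; an optional competing oxidized cofactor binds E with
    comp_ki and E.A with comp_km; substrate inhibition adds a dead-end
    E.A.B.B complex.
    """
    kia = p["ki_cofactor"] * p["km_g6p"] / p["km_cofactor"]
    e = 1.0
    ea = a / kia
    eb = b / p["ki_cofactor"]
    eab = (a / kia) * (b / p["km_cofactor"])
    species = {"E": e, "EA": ea, "EB": eb, "EAB": eab}
    # reduced cofactor(s) on free enzyme and on E.A
    species["EP"] = e * products / p["kic_product"]
    species["EAP"] = ea * products / p["kic_product"]
    if comp_ki is not None:
        species["EB2"] = e * comp_conc / comp_ki
        species["EAB2"] = ea * comp_conc / comp_km
    if p.get("kis_cofactor"):
        species["EABB"] = eab * b / p["kis_cofactor"]
    return species


def branch_rate_oracle(p: dict, a: float, b: float, products: float,
                       e0: float, comp_conc: float = 0.0,
                       comp_ki: float = None, comp_km: float = None) -> float:
    frac = species_fractions(branch_species(p, a, b, products,
                                            comp_conc, comp_ki, comp_km))
    return p["kcat"] * e0 * frac["EAB"]


def _params(branch) -> dict:
    return {"kcat": branch.kcat, "km_cofactor": branch.km_cofactor,
            "ki_cofactor": branch.ki_cofactor, "km_g6p": branch.km_g6p,
            "kic_product": branch.kic_product,
            "kis_cofactor": branch.kis_cofactor}


def dual_rates_oracle(enzyme, mix, mode: str) -> tuple:
    """(v_nadh, v_nadph) by explicit species enumeration."""
    pn, pp = _params(enzyme.nad), _params(enzyme.nadp)
    if mode == "independent":
        v_nadh = branch_rate_oracle(pn, mix.g6p, mix.nad_ox, mix.nadh, mix.e0,
                                    comp_conc=mix.nadp_ox,
                                    comp_ki=pp["ki_cofactor"],
                                    comp_km=pp["km_cofactor"])
        v_nadph = branch_rate_oracle(pp, mix.g6p, mix.nadp_ox, mix.nadph, mix.e0,
                                     comp_conc=mix.nad_ox,
                                     comp_ki=pn["ki_cofactor"],
                                     comp_km=pn["km_cofactor"])
        return v_nadh, v_nadph
    # shared pool: one enumeration, geometric-mean free-enzyme G6P constant
    kia_n = pn["ki_cofactor"] * pn["km_g6p"] / pn["km_cofactor"]
    kia_p = pp["ki_cofactor"] * pp["km_g6p"] / pp["km_cofactor"]
    kia = (kia_n * kia_p) ** 0.5
    ea = mix.g6p / kia
    species = {
        "E": 1.0,
        "EA": ea,
        "EB_nad": mix.nad_ox / pn["ki_cofactor"],
        "EB_nadp": mix.nadp_ox / pp["ki_cofactor"],
        "EP_nadh": mix.nadh / pn["kic_product"],
        "EP_nadph": mix.nadph / pp["kic_product"],
        "EAB_nad": ea * mix.nad_ox / pn["km_cofactor"],
        "EAB_nadp": ea * mix.nadp_ox / pp["km_cofactor"],
        "EAP_nadh": ea * mix.nadh / pn["kic_product"],
        "EAP_nadph": ea * mix.nadph / pp["kic_product"],
    }
    frac = species_fractions(species)
    return (pn["kcat"] * mix.e0 * frac["EAB_nad"],
            pp["kcat"] * mix.e0 * frac["EAB_nadp"])


def direct_linear_plot_oracle(points):
    """Brute-force all-pairs median of line intersections in (Km, Vmax)."""
    import statistics
    kms, vmaxs = [], []
    for (s1, v1), (s2, v2) in itertools.combinations(points, 2):
        if v1 / s1 == v2 / s2:
            continue
        km = (v2 - v1) / (v1 / s1 - v2 / s2)
        kms.append(km)
        vmaxs.append(v1 + (v1 / s1) * km)
    return statistics.median(kms), statistics.median(vmaxs)
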