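"""Seeded generators for every input class the pipeline consumes.

Three generators cover the three experimental data classes:

* :func:`gen_rate_dataset` — multi-concentration initial-rate designs with
  multiplicative noise, emulating a 96-well assay grid (cofactor 20-2,000 uM
  crossed with G6P 95-5,000 uM by default);
* :func:`gen_progress_curves` — product-accumulation time courses integrated
  from the mechanistic rate law, with optional first-order enzyme
  inactivation;
* :func:`gen_protein_set` — G6PDH-like protein cohorts with a planted
  N-terminal cofactor-binding fingerprint, a planted cofactor-discriminating
  anchor residue, background substitutions and indels, plus species/taxon
  mapping and glycolytic marker-gene tables.

Every generator is fully deterministic given its seed; independent
sub-streams are derived as ``default_rng([seed, k])`` with a documented
stream index k per purpose.  Each generator returns a machine-readable truth
table alongside the data so downstream estimates can be scored without
peeking at generator internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import InputError, UsageError
from .kinetics import AssayMix, Cofactor, CofactorBranch, branch_rate
from .fitting import ProgressCurve, RateDataset, RateObservation

__all__ = [
    "SynthKineticsSpec", "SynthSequenceSpec", "gen_rate_dataset",
    "gen_progress_curves", "gen_protein_set", "SynthProteinSet",
    "DEFAULT_COFACTOR_DESIGN", "DEFAULT_G6P_DESIGN",
]

# assay design grid defaults (uM)
DEFAULT_COFACTOR_DESIGN = (20.0, 50.0, 100.0, 200.0, 500.0, 1000.0, 2000.0)
DEFAULT_G6P_DESIGN = (95.0, 300.0, 1000.0, 3000.0, 5000.0)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# sub-stream indices appended to the user seed
_STREAM_RATE_NOISE = 0
_STREAM_SCAFFOLD = 1
_STREAM_ANCHOR = 2
_STREAM_SUBSTITUTION = 3
_STREAM_INDEL = 4
_STREAM_CATEGORY = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# Initial-rate data


@dataclass(frozen=True)
class SynthKineticsSpec:
    """Design and noise model for one synthetic initial-rate experiment."""

    true_branch: CofactorBranch
    cofactor_design: tuple = DEFAULT_COFACTOR_DESIGN
    g6p_design: tuple = DEFAULT_G6P_DESIGN
    product_design: tuple = (0.0,)  # reduced-cofactor levels added to the mix
    e0: float = 0.01  # uM enzyme
    noise_cv: float = 0.05
    replicates: int = 1
    seed: int = 0
    enzyme_name: str = "synthetic"

    def __post_init__(self):
        if self.noise_cv < 0:
            raise UsageError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise UsageError("replicates must be >= 1")
        if len(self.cofactor_design) == 0 or len(self.g6p_design) == 0:
            raise UsageError("design grid must be non-empty")
        if self.e0 <= 0:
            raise UsageError("e0 must be positive")


def gen_rate_dataset(spec: SynthKineticsSpec) -> tuple[RateDataset, pd.DataFrame]:
    """Initial rates on the design grid with truncated multiplicative noise.

    v_obs = v_true * (1 + eps), eps ~ Normal(0, noise_cv^2) truncated at -0.9
    so observed rates stay positive.  The truth table carries one row of the
    generating parameter values plus the per-observation true rates.
    """
    rng = _rng(spec.seed, _STREAM_RATE_NOISE)
    branch = spec.true_branch
    is_nad = branch.cofactor_id is Cofactor.NAD
    observations = []
    true_rates = []
    for rep in range(spec.replicates):
        for g6p in spec.g6p_design:
            for b in spec.cofactor_design:
                for p in spec.product_design:
                    mix = AssayMix(
                        g6p=g6p,
                        nad_ox=b if is_nad else 0.0,
                        nadp_ox=0.0 if is_nad else b,
                        nadh=p if is_nad else 0.0,
                        nadph=0.0 if is_nad else p,
                        e0=spec.e0,
                    )
                    v_true = branch_rate(branch, mix)
                    eps = max(float(rng.normal(0.0, spec.noise_cv)), -0.9) \
                        if spec.noise_cv > 0 else 0.0
                    observations.append(RateObservation(
                        mix=mix, v0=v_true * (1.0 + eps),
                        replicate_id=f"rep{rep + 1}"))
                    true_rates.append(v_true)
    dataset = RateDataset(observations=tuple(observations),
                          enzyme_name=spec.enzyme_name,
                          cofactor=branch.cofactor_id)
    truth = pd.DataFrame([{
        "kcat": branch.kcat, "km_cofactor": branch.km_cofactor,
        "ki_cofactor": branch.ki_cofactor, "km_g6p": branch.km_g6p,
        "kic_product": branch.kic_product,
        "kis_cofactor": branch.kis_cofactor,
        "noise_cv": spec.noise_cv, "seed": spec.seed,
    }])
    truth.attrs["true_rates"] = np.array(true_rates)
    return dataset, truth


# ---------------------------------------------------------------------------
# Progress curves


def gen_progress_curves(true_branch: CofactorBranch, mix: AssayMix,
                        e0_list: Sequence[float], duration: float,
                        n_points: int = 50, decay_rate: float = 0.0,
                        rel_tol: float = 1e-6,
                        seed: int = 0) -> tuple[list[ProgressCurve], pd.DataFrame]:
    """Integrate d[product]/dt = v(state) for each enzyme concentration.

    Substrate and oxidized cofactor are consumed stoichiometrically and the
    reduced cofactor accumulates (feeding product inhibition); the enzyme
    decays as e0*exp(-decay_rate*t) when requested.  Curves are noiseless —
    measurement noise belongs to the rate-data generator.
    """
    if duration <= 0:
        raise UsageError("duration must be positive")
    if n_points < 5:
        raise UsageError("n_points must be >= 5")
    if decay_rate < 0:
        raise UsageError("decay_rate must be >= 0")
    is_nad = true_branch.cofactor_id is Cofactor.NAD
    b0 = mix.nad_ox if is_nad else mix.nadp_ox
    p_base = mix.nadh if is_nad else mix.nadph
    if mix.g6p <= 0 or b0 <= 0:
        raise UsageError("mix must contain G6P and the branch's oxidized cofactor")
    s_limit = min(mix.g6p, b0)
    times = np.linspace(0.0, duration, n_points)
    curves = []
    rows = []
    for e0 in e0_list:
        if e0 <= 0:
            raise UsageError("e0 values must be positive")

        def rhs(t, y):
            p = min(max(y[0], 0.0), s_limit * (1 - 1e-12))
            state = AssayMix(
                g6p=mix.g6p - p,
                nad_ox=(b0 - p) if is_nad else 0.0,
                nadp_ox=0.0 if is_nad else (b0 - p),
                nadh=(p_base + p) if is_nad else mix.nadh,
                nadph=mix.nadph if is_nad else (p_base + p),
                e0=e0,
            )
            return [branch_rate(true_branch, state) * math.exp(-decay_rate * t)]

        sol = solve_ivp(rhs, (0.0, duration), [0.0], t_eval=times,
                        method="LSODA", rtol=rel_tol,
                        atol=rel_tol * max(s_limit, 1.0) * 1e-3)
        if not sol.success:
            raise InputError(f"progress-curve integration failed: {sol.message}")
        product = np.maximum.accumulate(np.clip(sol.y[0], 0.0, s_limit))
        curve_mix = AssayMix(g6p=mix.g6p, nad_ox=mix.nad_ox, nadp_ox=mix.nadp_ox,
                             nadh=mix.nadh, nadph=mix.nadph, e0=e0)
        curves.append(ProgressCurve(times=tuple(times), product=tuple(product),
                                    mix=curve_mix, s0=s_limit))
        rows.append({"e0": e0, "decay_rate": decay_rate, "s0": s_limit,
                     "v0_true": rhs(0.0, [0.0])[0], "seed": seed})
    return curves, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Protein cohorts


@dataclass(frozen=True)
class SynthSequenceSpec:
    """Cohort layout and mutation model for synthetic G6PDH protein sets."""

    n_species: int = 50
    isoform_count_distribution: dict = field(
        default_factory=lambda: {1: 0.3, 2: 0.4, 3: 0.2, 4: 0.1})
    anchor_residue_distribution: dict = field(
        default_factory=lambda: {"R": 0.7, "H": 0.2, "K": 0.1})
    substitution_rate: float = 0.0  # per-site Bernoulli rate
    indel_rate: float = 0.0  # per-site; round(rate * length) events per record
    glycolysis_mixture: dict = field(
        default_factory=lambda: {"ED": 0.4, "EMP": 0.3, "ED_EMP": 0.2, "other": 0.1})
    taxa: tuple = ("Taxon_A", "Taxon_B")
    scaffold_length: int = 500
    anchor_pos: int = 50  # 1-based, echoing the R50 convention
    fingerprint_pos: int = 12  # 1-based position of the leading fingerprint G
    seed: int = 0

    def __post_init__(self):
        for name in ("isoform_count_distribution", "anchor_residue_distribution",
                     "glycolysis_mixture"):
            dist = getattr(self, name)
            if not dist or any(p < 0 for p in dist.values()):
                raise UsageError(f"{name} must be a non-negative distribution")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise UsageError(f"{name} must sum to 1")
        for name in ("substitution_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.2:
                raise UsageError(f"{name} must lie in [0, 0.2]")
        if self.n_species < 1:
            raise UsageError("n_species must be >= 1")


class SynthProteinSet(NamedTuple):
    records: list  # of (record_id, sequence)
    mapping: pd.DataFrame  # record_id, species, taxon
    markers: pd.DataFrame  # species, pfk, edd, eda
    truth: pd.DataFrame  # per-record planted values
    reference: str  # clean scaffold sequence with R at the anchor


_FINGERPRINT_CHOICES = ("G", "GA", None, "G", "D", "L", "AV", "KL")
_MARKER_FLAGS = {"ED": (0, 1, 1), "EMP": (1, 0, 0), "ED_EMP": (1, 1, 1),
                 "other": (0, 0, 0)}


def _build_scaffold(spec: SynthSequenceSpec, rng: np.random.Generator) -> list[str]:
    seq = list(rng.choice(list(AMINO_ACIDS), size=spec.scaffold_length))
    fp0 = spec.fingerprint_pos - 1
    for off, choices in enumerate(_FINGERPRINT_CHOICES):
        if choices is not None:
            seq[fp0 + off] = choices[int(rng.integers(len(choices)))]
    seq[spec.anchor_pos - 1] = "R"
    return seq


def _protected_positions(spec: SynthSequenceSpec) -> set[int]:
    """0-based scaffold positions that substitutions must avoid."""
    fp0 = spec.fingerprint_pos - 1
    return set(range(fp0, fp0 + 8)) | {spec.anchor_pos - 1}


def _indel_forbidden(spec: SynthSequenceSpec) -> set[int]:
    """0-based positions where indels may not start (anchor +/- 10 and the
    fingerprint block)."""
    fp0 = spec.fingerprint_pos - 1
    a0 = spec.anchor_pos - 1
    return set(range(fp0, fp0 + 8)) | set(range(max(0, a0 - 10), a0 + 11))


def _mutate(scaffold: list[str], anchor_residue: str, spec: SynthSequenceSpec,
            rng_sub: np.random.Generator,
            rng_indel: np.random.Generator) -> tuple[str, int, int]:
    """One record's sequence plus the 1-based planted anchor and
    fingerprint positions after indels."""
    seq = list(scaffold)
    seq[spec.anchor_pos - 1] = anchor_residue
    protected = _protected_positions(spec)
    if spec.substitution_rate > 0:
        hits = np.nonzero(rng_sub.random(len(seq)) < spec.substitution_rate)[0]
        for i in hits:
            if int(i) in protected:
                continue
            alternatives = AMINO_ACIDS.replace(seq[i], "")
            seq[i] = alternatives[int(rng_sub.integers(len(alternatives)))]
    anchor0 = spec.anchor_pos - 1
    fp0 = spec.fingerprint_pos - 1
    if spec.indel_rate > 0:
        n_events = min(int(round(spec.indel_rate * spec.scaffold_length)), 3)
        for _ in range(n_events):
            forbidden = set(range(fp0, fp0 + 8)) | \
                set(range(max(0, anchor0 - 10), anchor0 + 11))
            length = int(rng_indel.integers(1, 6))
            if rng_indel.random() < 0.5:  # deletion
                allowed = [i for i in range(len(seq) - length)
                           if not (set(range(i, i + length)) & forbidden)]
                if not allowed:
                    continue
                pos = int(allowed[int(rng_indel.integers(len(allowed)))])
                del seq[pos:pos + length]
                if pos < anchor0:
                    anchor0 -= length
                if pos < fp0:
                    fp0 -= length
            else:  # insertion
                allowed = [i for i in range(len(seq)) if i not in forbidden]
                if not allowed:
                    continue
                pos = int(allowed[int(rng_indel.integers(len(allowed)))])
                insert = [AMINO_ACIDS[int(rng_indel.integers(20))]
                          for _ in range(length)]
                seq[pos:pos] = insert
                if pos <= anchor0:
                    anchor0 += length
                if pos <= fp0:
                    fp0 += length
    return "".join(seq), anchor0 + 1, fp0 + 1


def gen_protein_set(spec: SynthSequenceSpec) -> SynthProteinSet:
    """Protein cohort with planted anchor residues, fingerprint, and markers.

    Substitutions avoid the anchor and fingerprint; indels start outside a
    +/-10 window of the anchor, so the planted anchor stays recoverable by
    alignment.  The truth table records, per record, the planted anchor
    residue and its 1-based position in the final sequence, and per species
    the glycolytic category.
    """
    rng_scaffold = _rng(spec.seed, _STREAM_SCAFFOLD)
    rng_anchor = _rng(spec.seed, _STREAM_ANCHOR)
    rng_sub = _rng(spec.seed, _STREAM_SUBSTITUTION)
    rng_indel = _rng(spec.seed, _STREAM_INDEL)
    rng_cat = _rng(spec.seed, _STREAM_CATEGORY)

    scaffold = _build_scaffold(spec, rng_scaffold)
    reference = "".join(scaffold)

    iso_counts = sorted(spec.isoform_count_distribution)
    iso_probs = [spec.isoform_count_distribution[k] for k in iso_counts]
    anchors = sorted(spec.anchor_residue_distribution)
    anchor_probs = [spec.anchor_residue_distribution[a] for a in anchors]
    cats = sorted(spec.glycolysis_mixture)
    cat_probs = [spec.glycolysis_mixture[c] for c in cats]

    records, map_rows, marker_rows, truth_rows = [], [], [], []
    for i in range(spec.n_species):
        species = f"Species_{i:04d}"
        taxon = spec.taxa[i % len(spec.taxa)]
        n_iso = int(rng_anchor.choice(iso_counts, p=iso_probs))
        category = str(rng_cat.choice(cats, p=cat_probs))
        pfk, edd, eda = _MARKER_FLAGS[category]
        marker_rows.append({"species": species, "pfk": pfk, "edd": edd,
                            "eda": eda})
        for j in range(n_iso):
            record_id = f"{species}_iso{j + 1}"
            residue = str(rng_anchor.choice(anchors, p=anchor_probs))
            seq, anchor_pos, fp_pos = _mutate(scaffold, residue, spec,
                                              rng_sub, rng_indel)
            records.append((record_id, seq))
            map_rows.append({"record_id": record_id, "species": species,
                             "taxon": taxon})
            truth_rows.append({
                "record_id": record_id, "species": species, "taxon": taxon,
                "anchor_residue": residue, "anchor_pos": anchor_pos,
                "n_isoforms": n_iso, "glycolysis": category,
                "fingerprint_pos": fp_pos,
            })
    return SynthProteinSet(
        records=records,
        mapping=pd.DataFrame(map_rows),
        markers=pd.DataFrame(marker_rows),
        truth=pd.DataFrame(truth_rows),
        reference=reference,
    )
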