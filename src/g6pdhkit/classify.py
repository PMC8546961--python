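"""Residue-anchored cofactor-specificity classification of G6PDH sequences.

Bacterial G6PDHs discriminate NADP+ from NAD+ largely through one residue in
the beta2-alpha2 loop that hydrogen-bonds the 2'-phosphate of NADP+ (R72 in
the T. cruzi enzyme; the R50-equivalent of the E. coli enzyme).  The rule
implemented here: a query whose residue at the anchor-equivalent position is
arginine is called NADP-specific; any other residue is called relaxed
(loosened cofactor discrimination); a gap, an X, or a failed mapping is
unresolved.

The anchor position is located by deterministic pairwise global alignment of
each query to an anchored reference (affine gaps, BLOSUM62), rather than by
per-order multiple alignment.  Classifications are rolled up per species
(isoform counts, presence of a relaxed isozyme) and joined with glycolytic
marker genes — 6-phosphofructo-1-kinase (Pfk) for the EMP pathway, KDPG
aldolase (Eda, optionally also the dehydratase Edd) for the ED pathway — to
give taxon-level summaries of how isozyme multiplicity and cofactor
specificity co-vary with glycolytic strategy.

Coordinates are 1-based and inclusive on ungapped sequences throughout.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InputError, UsageError

__all__ = [
    "ProteinRecord", "AnchorReference", "CofactorCall", "Call",
    "SpeciesProfile", "GenomeMarkers", "TaxonSummary", "Glycolysis",
    "align_to_reference", "call_cofactor", "detect_fingerprint",
    "check_conserved_residues", "position_frequency_matrix",
    "build_species_profiles", "classify_glycolysis", "summarize_taxon",
    "anchor_window", "classify_records", "calls_from_alignment",
]

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")

# Conserved catalytic/substrate-binding sites of the L. mesenteroides enzyme
# (1-based positions in that reference numbering) used as a sanity screen.
LM_CONSERVED_SITES = {"R176": (176, "R"), "E146": (146, "E"),
                      "Y415": (415, "Y"), "H240": (240, "H")}


class Call(str, enum.Enum):
    NADP_SPECIFIC = "NADP_specific"
    RELAXED = "relaxed"
    UNRESOLVED = "unresolved"


class Glycolysis(str, enum.Enum):
    ED = "ED"
    EMP = "EMP"
    ED_EMP = "ED_EMP"
    OTHER = "other"


ISOFORM_BINS = ("1", "2", "3", "4plus")


def _isoform_bin(n: int) -> str:
    return str(n) if n < 4 else "4plus"


@dataclass(frozen=True)
class ProteinRecord:
    record_id: str
    sequence: str
    species: str = ""
    taxon: str = ""

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise InputError(f"{self.record_id}: empty sequence")
        bad = set(seq) - _VALID_AA
        if bad:
            raise InputError(
                f"{self.record_id}: invalid characters {sorted(bad)} "
                "(gaps are not allowed on input)")


@dataclass(frozen=True)
class AnchorReference:
    """A reference protein with a known cofactor-discriminating position."""

    name: str
    sequence: str
    anchor_pos: int  # 1-based
    expected_residue: str = "R"

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not 1 <= self.anchor_pos <= len(seq):
            raise InputError("anchor_pos outside the reference sequence")
        found = seq[self.anchor_pos - 1]
        if found != self.expected_residue:
            raise InputError(
                f"reference residue at anchor_pos is {found}, "
                f"expected {self.expected_residue}")


@dataclass(frozen=True)
class CofactorCall:
    record_id: str
    call: Call
    mapped_pos: Optional[int] = None  # 1-based query position
    residue: str = "-"
    fingerprint_found: bool = False
    fingerprint_offset: Optional[int] = None
    conserved_hits: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GenomeMarkers:
    species: str
    has_pfk: bool
    has_edd: bool
    has_eda: bool


@dataclass(frozen=True)
class SpeciesProfile:
    species: str
    taxon: str
    n_isoforms: int
    bin: str
    has_relaxed: bool
    glycolysis: Glycolysis

    def __post_init__(self):
        if self.n_isoforms < 1:
            raise InputError("a species profile needs at least one isoform")
        if self.bin != _isoform_bin(self.n_isoforms):
            raise InputError("bin inconsistent with n_isoforms")


@dataclass
class TaxonSummary:
    taxon: str
    species_count: int
    bin_fractions: dict  # bin -> fraction of species
    relaxed_within_bin: dict  # bin -> fraction of that bin's species with a relaxed isozyme
    glycolysis_fractions: dict  # category -> fraction of species
    crosstab: pd.DataFrame  # glycolysis (rows) x bin (columns), fractions of species


# ---------------------------------------------------------------------------
# Alignment and per-sequence calls


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def align_to_reference(query: ProteinRecord, ref: AnchorReference) -> Optional[int]:
    """Map the reference anchor column onto the query by global alignment.

    Returns the 1-based query position aligned to ``ref.anchor_pos``, or
    ``None`` when that column is a gap in the query.  X residues score as a
    wildcard under BLOSUM62.
    """
    if not query.sequence:
        raise InputError("empty query sequence")
    alignment = _ALIGNER.align(ref.sequence, query.sequence)[0]
    target0 = ref.anchor_pos - 1
    for (t_start, t_end), (q_start, q_end) in zip(*alignment.aligned):
        if t_start <= target0 < t_end:
            return q_start + (target0 - t_start) + 1
    return None


def call_cofactor(query: ProteinRecord, ref: AnchorReference,
                  fingerprint_window: int = 60,
                  conserved: Optional["ConservedReference"] = None) -> CofactorCall:
    """Classify one sequence by its residue at the anchor-equivalent position.

    R -> NADP_specific; any other residue -> relaxed; gap or X or failed
    mapping -> unresolved.
    """
    mapped = align_to_reference(query, ref)
    if mapped is None:
        call, residue = Call.UNRESOLVED, "-"
    else:
        residue = query.sequence[mapped - 1]
        if residue == "X":
            call = Call.UNRESOLVED
        elif residue == ref.expected_residue:
            call = Call.NADP_SPECIFIC
        else:
            call = Call.RELAXED
    found, offset = detect_fingerprint(query, window=fingerprint_window)
    hits = check_conserved_residues(query, conserved) if conserved else {}
    return CofactorCall(record_id=query.record_id, call=call, mapped_pos=mapped,
                        residue=residue, fingerprint_found=found,
                        fingerprint_offset=offset, conserved_hits=hits)


_FINGERPRINT_RE = re.compile(r"G[GA].GDL[AV][KL]")


def detect_fingerprint(query: ProteinRecord | str,
                       window: int = 60) -> tuple[bool, Optional[int]]:
    """Scan the N terminus for the cofactor-binding fingerprint
    G-[G/A]-X-G-D-L-[A/V]-[K/L]; returns (found, 1-based offset of the
    leading G of the first match)."""
    seq = query.sequence if isinstance(query, ProteinRecord) else query.upper()
    if len(seq) < 8:
        return False, None
    m = _FINGERPRINT_RE.search(seq[:window])
    if m is None:
        return False, None
    return True, m.start() + 1


@dataclass(frozen=True)
class ConservedReference:
    """A reference sequence plus named 1-based positions to screen."""

    name: str
    sequence: str
    sites: dict  # site name -> (1-based position, expected residue)

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        for site, (pos, res) in self.sites.items():
            if not 1 <= pos <= len(seq):
                raise InputError(f"site {site} outside the reference")
            if seq[pos - 1] != res:
                raise InputError(f"site {site}: reference has {seq[pos - 1]}, "
                                 f"expected {res}")


def check_conserved_residues(query: ProteinRecord,
                             ref: ConservedReference) -> dict:
    """True/False per named site; ``None`` marks sites whose reference column
    is unmapped in the query (e.g. the query is too short)."""
    alignment = _ALIGNER.align(ref.sequence, query.sequence)[0]
    blocks = list(zip(*alignment.aligned))
    out = {}
    for site, (pos, expected) in ref.sites.items():
        target0 = pos - 1
        mapped = None
        for (t_start, t_end), (q_start, q_end) in blocks:
            if t_start <= target0 < t_end:
                mapped = q_start + (target0 - t_start)
                break
        if mapped is None:
            out[site] = None
        else:
            out[site] = query.sequence[mapped] == expected
    return out


def calls_from_alignment(aligned: dict, ref_name: str, anchor_pos: int,
                         expected_residue: str = "R") -> list[CofactorCall]:
    """Cofactor calls from a pre-computed multiple alignment.

    ``aligned`` maps record names to equal-width gapped rows ('-' gaps);
    ``anchor_pos`` is 1-based in the UNGAPPED reference row named
    ``ref_name``.  The anchor column is located in the reference row and the
    residue of every other row in that column is classified with the same
    rule as :func:`call_cofactor`.
    """
    if ref_name not in aligned:
        raise InputError(f"reference row {ref_name!r} absent from alignment")
    widths = {len(s) for s in aligned.values()}
    if len(widths) != 1:
        raise InputError("alignment rows must all have the same width")
    ref_row = aligned[ref_name].upper()
    seen = 0
    column = None
    for i, ch in enumerate(ref_row):
        if ch != "-":
            seen += 1
            if seen == anchor_pos:
                column = i
                break
    if column is None:
        raise InputError("anchor_pos beyond the ungapped reference length")
    if ref_row[column] != expected_residue:
        raise InputError(
            f"reference anchor residue is {ref_row[column]}, "
            f"expected {expected_residue}")
    calls = []
    for name, row in aligned.items():
        if name == ref_name:
            continue
        row = row.upper()
        residue = row[column]
        if residue in ("-", "X"):
            call, mapped = Call.UNRESOLVED, None
            residue = "-" if residue == "-" else "X"
        else:
            mapped = sum(1 for ch in row[:column + 1] if ch != "-")
            call = (Call.NADP_SPECIFIC if residue == expected_residue
                    else Call.RELAXED)
        calls.append(CofactorCall(record_id=name, call=call,
                                  mapped_pos=mapped, residue=residue))
    return calls


def anchor_window(query: ProteinRecord, mapped_pos: int, flank: int = 7) -> str:
    """Ungapped window around the mapped anchor, padded with '-' at the ends,
    suitable as a position-frequency-matrix row."""
    seq = query.sequence
    i0 = mapped_pos - 1
    lo, hi = i0 - flank, i0 + flank + 1
    left_pad = "-" * max(0, -lo)
    right_pad = "-" * max(0, hi - len(seq))
    return left_pad + seq[max(0, lo):min(len(seq), hi)] + right_pad


def position_frequency_matrix(segments: Sequence[str]) -> pd.DataFrame:
    """Per-column residue frequencies of equal-width aligned segments.

    Rows are the 20 amino acids plus '-' (gap) and 'X'; every column sums
    to 1.  Suitable as sequence-logo input.
    """
    if len(segments) == 0:
        raise InputError("position_frequency_matrix needs at least one segment")
    width = len(segments[0])
    if any(len(s) != width for s in segments):
        raise InputError("segments must all have the same aligned width")
    alphabet = list("ACDEFGHIKLMNPQRSTVWY") + ["X", "-"]
    counts = pd.DataFrame(0.0, index=alphabet, columns=range(1, width + 1))
    for seg in segments:
        for col, ch in enumerate(seg.upper(), start=1):
            if ch not in counts.index:
                raise InputError(f"unexpected character {ch!r} in segment")
            counts.loc[ch, col] += 1.0
    return counts / len(segments)


# ---------------------------------------------------------------------------
# Species and taxon rollups


def classify_glycolysis(m: GenomeMarkers, ed_rule: str = "eda_only") -> Glycolysis:
    """Glycolytic strategy from marker genes.

    ED capability is signalled by KDPG aldolase (``eda_only``, the default)
    or by either ED signature enzyme (``edd_or_eda``); EMP capability by Pfk.
    Both -> ED_EMP; neither -> other.
    """
    if ed_rule not in ("eda_only", "edd_or_eda"):
        raise UsageError(f"unknown ed_rule {ed_rule!r}")
    ed = m.has_eda if ed_rule == "eda_only" else (m.has_eda or m.has_edd)
    if ed and m.has_pfk:
        return Glycolysis.ED_EMP
    if ed:
        return Glycolysis.ED
    if m.has_pfk:
        return Glycolysis.EMP
    return Glycolysis.OTHER


def build_species_profiles(records: Sequence[ProteinRecord],
                           calls: Sequence[CofactorCall],
                           markers: Sequence[GenomeMarkers],
                           ed_rule: str = "eda_only") -> list[SpeciesProfile]:
    """Roll per-record calls up to one profile per species.

    Unresolved calls count toward the isoform number but never toward
    ``has_relaxed``.  A species without a marker row gets glycolysis
    ``other`` with a warning.
    """
    call_by_id = {c.record_id: c for c in calls}
    marker_by_species = {}
    for m in markers:
        if m.species in marker_by_species:
            raise InputError(f"duplicate marker row for species {m.species}")
        marker_by_species[m.species] = m
    by_species: dict[str, list[ProteinRecord]] = {}
    taxon_of: dict[str, str] = {}
    for rec in records:
        if not rec.species:
            raise InputError(f"{rec.record_id}: record lacks a species label")
        by_species.setdefault(rec.species, []).append(rec)
        taxon_of.setdefault(rec.species, rec.taxon)
    profiles = []
    for species in sorted(by_species):
        recs = by_species[species]
        n = len(recs)
        has_relaxed = any(
            call_by_id[r.record_id].call is Call.RELAXED
            for r in recs if r.record_id in call_by_id)
        if species in marker_by_species:
            glyc = classify_glycolysis(marker_by_species[species], ed_rule)
        else:
            import warnings
            warnings.warn(f"species {species} has no marker row; "
                          "glycolysis set to 'other'", stacklevel=2)
            glyc = Glycolysis.OTHER
        profiles.append(SpeciesProfile(
            species=species, taxon=taxon_of[species], n_isoforms=n,
            bin=_isoform_bin(n), has_relaxed=has_relaxed, glycolysis=glyc))
    return profiles


def summarize_taxon(profiles: Sequence[SpeciesProfile]) -> list[TaxonSummary]:
    """Per-taxon fractions by isoform bin, relaxed-within-bin, glycolytic
    category, and the glycolysis x bin cross-tab.  Each partition sums to 1
    over its support."""
    if len(profiles) == 0:
        raise UsageError("summarize_taxon needs at least one profile")
    df = pd.DataFrame([{
        "taxon": p.taxon, "species": p.species, "bin": p.bin,
        "has_relaxed": p.has_relaxed, "glycolysis": p.glycolysis.value,
    } for p in profiles])
    cats = [g.value for g in Glycolysis]
    out = []
    for taxon in sorted(df["taxon"].unique()):
        sub = df[df["taxon"] == taxon]
        n = len(sub)
        bin_fracs = {b: float((sub["bin"] == b).sum()) / n for b in ISOFORM_BINS}
        relaxed = {}
        for b in ISOFORM_BINS:
            in_bin = sub[sub["bin"] == b]
            relaxed[b] = (float(in_bin["has_relaxed"].sum()) / len(in_bin)
                          if len(in_bin) else float("nan"))
        glyc_fracs = {c: float((sub["glycolysis"] == c).sum()) / n for c in cats}
        ct = pd.crosstab(sub["glycolysis"], sub["bin"]).reindex(
            index=cats, columns=ISOFORM_BINS, fill_value=0).astype(float) / n
        out.append(TaxonSummary(
            taxon=taxon, species_count=n, bin_fractions=bin_fracs,
            relaxed_within_bin=relaxed, glycolysis_fractions=glyc_fracs,
            crosstab=ct))
    return out


def classify_records(records: Sequence[ProteinRecord], ref: AnchorReference,
                     fingerprint_window: int = 60,
                     conserved: Optional[ConservedReference] = None
                     ) -> tuple[list[CofactorCall], pd.DataFrame]:
    """Classify every record; returns the calls and a tidy calls table."""
    calls = [call_cofactor(r, ref, fingerprint_window, conserved)
             for r in records]
    table = pd.DataFrame([{
        "record_id": c.record_id,
        "species": r.species,
        "taxon": r.taxon,
        "mapped_pos": c.mapped_pos,
        "residue": c.residue,
        "call": c.call.value,
        "fingerprint_found": c.fingerprint_found,
        "fingerprint_offset": c.fingerprint_offset,
    } for r, c in zip(records, calls)])
    return calls, table
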