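"""Configuration-driven orchestration with reproducible run manifests.

A run config is a mapping with a global ``seed``, an ``out_dir`` and any of
the stage sections ``phi``, ``simulate``, ``fit``, ``selwyn``, ``classify``
and ``synth``.  Stages execute in that fixed order; every output file is
listed in the manifest with a SHA-256 checksum, so a rerun with the same
config and seed reproduces the checksums of all deterministic stages.
Stage-specific random streams are derived from the single global seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import AnchorReference, ProteinRecord, build_species_profiles, \
    classify_records, summarize_taxon
from .errors import G6pdhkitError, ValidationError
from .fitting import ModelSpec, bootstrap_ci, global_fit, selwyn_test
from .io import read_markers, read_progress_curves, read_protein_fasta, \
    read_rate_dataset, write_protein_fasta, write_rate_dataset, write_tsv
from .kinetics import load_params, load_kt2440, specificity_constant
from .redox import GridSpec, compare_enzymes, default_grid, simulate_grid
from .synth import SynthKineticsSpec, SynthSequenceSpec, gen_protein_set, \
    gen_rate_dataset

log = logging.getLogger("g6pdhkit")

_STAGE_ORDER = ("phi", "simulate", "fit", "selwyn", "classify", "synth")
_GLOBAL_KEYS = {"seed", "out_dir", "log_level"}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(config: dict) -> dict:
    """Schema check; raises :class:`ValidationError` before any stage runs."""
    if not isinstance(config, dict) or not config:
        raise ValidationError("config must be a non-empty mapping")
    unknown = set(config) - _GLOBAL_KEYS - set(_STAGE_ORDER)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    stages = [s for s in _STAGE_ORDER if s in config]
    if not stages:
        raise ValidationError("config requests no stages")
    seed = config.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        raise ValidationError("seed must be a non-negative integer")
    # referenced input files must exist up front
    for stage in stages:
        section = config[stage] or {}
        if not isinstance(section, dict):
            raise ValidationError(f"section {stage!r} must be a mapping")
        for key in ("params", "data", "curves", "fasta", "mapping", "markers",
                    "ref_fasta"):
            if key in section and section[key] is not None:
                if not Path(section[key]).exists():
                    raise ValidationError(
                        f"{stage}.{key}: file not found: {section[key]}")
    return config


def _load_enzymes(section: dict) -> dict:
    if section.get("params"):
        return load_params(section["params"])
    return load_kt2440()


def run(config: dict, out_dir=None) -> dict:
    """Execute the requested stages and return (and write) the run manifest."""
    config = validate_config(config)
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(
        logging, str(config.get("log_level", "INFO")).upper(), logging.INFO))
    manifest = {"version": __version__, "seed": seed, "stages": {},
                "outputs": []}

    def record(stage: str, path: Path):
        # paths are stored relative to the run directory so the manifest
        # stays portable alongside its outputs
        manifest["outputs"].append({
            "stage": stage, "path": str(Path(path).relative_to(out)),
            "sha256": _sha256(Path(path))})

    for stage in (s for s in _STAGE_ORDER if s in config):
        section = config[stage] or {}
        log.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](section, seed, out, record)
            manifest["stages"][stage] = "ok"
        except G6pdhkitError as exc:
            log.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = f"failed: {exc}"
            break
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_phi(section, seed, out, record):
    enzymes = _load_enzymes(section)
    df = pd.DataFrame([{"enzyme": name, "phi": specificity_constant(e)}
                       for name, e in enzymes.items()])
    path = out / "phi.tsv"
    write_tsv(df, path)
    record("phi", path)


def _stage_simulate(section, seed, out, record):
    enzymes = _load_enzymes(section)
    names = section.get("enzymes") or list(enzymes)
    mode = section.get("mode", "independent")
    if "grid" in section and section["grid"]:
        g = dict(section["grid"])
        grid = GridSpec(
            nad_ratio_axis=g["nad_ratio_axis"],
            nadp_ratio_axis=g["nadp_ratio_axis"],
            g6p_levels=g.get("g6p_levels", (100.0, 1000.0)),
            nad_pool_total=g.get("nad_pool_total", 2600.0),
            nadp_pool_total=g.get("nadp_pool_total", 400.0),
            e0=g.get("e0", 1.0), mode=mode)
    else:
        grid = default_grid(mode=mode)
    for name in names:
        surface = simulate_grid(enzymes[name], grid)
        path = out / f"surface_{name}.tsv"
        write_tsv(surface.to_frame(), path)
        record("simulate", path)
    path = out / "enzyme_comparison.tsv"
    write_tsv(compare_enzymes([enzymes[n] for n in names], grid), path)
    record("simulate", path)


def _stage_fit(section, seed, out, record):
    data = read_rate_dataset(section["data"])
    model = ModelSpec(
        product_inhibition=bool(section.get("product_inhibition", False)),
        substrate_inhibition=bool(section.get("substrate_inhibition", False)),
        enzyme_decay=bool(section.get("enzyme_decay", False)))
    fit = global_fit(data, model, seed=seed)
    n_boot = int(section.get("n_boot", 0))
    if n_boot > 0:
        fit = bootstrap_ci(data, model, fit, n_boot=n_boot, seed=seed)
    path = out / "fit.json"
    path.write_text(fit.to_json())
    record("fit", path)


def _stage_selwyn(section, seed, out, record):
    curves = read_progress_curves(section["curves"])
    statistic, verdict = selwyn_test(
        curves, threshold=float(section.get("threshold", 0.05)))
    path = out / "selwyn.json"
    path.write_text(json.dumps({"statistic": statistic, "verdict": verdict},
                               indent=2))
    record("selwyn", path)


def _stage_classify(section, seed, out, record):
    mapping = pd.read_csv(section["mapping"], sep="\t") if section.get("mapping") else None
    records = read_protein_fasta(section["fasta"], mapping)
    if section.get("ref_fasta"):
        ref_rec = read_protein_fasta(section["ref_fasta"])[0]
        ref = AnchorReference(name=ref_rec.record_id, sequence=ref_rec.sequence,
                              anchor_pos=int(section["anchor_pos"]))
    else:
        raise ValidationError("classify stage needs ref_fasta and anchor_pos")
    calls, table = classify_records(
        records, ref, fingerprint_window=int(section.get("window", 60)))
    path = out / "calls.tsv"
    write_tsv(table, path)
    record("classify", path)
    if section.get("markers"):
        markers = read_markers(section["markers"])
        profiles = build_species_profiles(
            records, calls, markers, ed_rule=section.get("ed_rule", "eda_only"))
        pdf = pd.DataFrame([{
            "species": p.species, "taxon": p.taxon, "n_isoforms": p.n_isoforms,
            "bin": p.bin, "has_relaxed": p.has_relaxed,
            "glycolysis": p.glycolysis.value} for p in profiles])
        path = out / "profiles.tsv"
        write_tsv(pdf, path)
        record("classify", path)
        rows = []
        for ts in summarize_taxon(profiles):
            for b, f in ts.bin_fractions.items():
                rows.append({"taxon": ts.taxon, "partition": "isoform_bin",
                             "category": b, "fraction": f})
            for c, f in ts.glycolysis_fractions.items():
                rows.append({"taxon": ts.taxon, "partition": "glycolysis",
                             "category": c, "fraction": f})
        path = out / "taxon_summary.tsv"
        write_tsv(pd.DataFrame(rows), path)
        record("classify", path)


def _stage_synth(section, seed, out, record):
    kind = section.get("kind", "proteins")
    if kind == "proteins":
        spec = SynthSequenceSpec(
            n_species=int(section.get("n_species", 50)),
            substitution_rate=float(section.get("substitution_rate", 0.0)),
            indel_rate=float(section.get("indel_rate", 0.0)),
            seed=seed)
        bundle = gen_protein_set(spec)
        write_protein_fasta(bundle.records, out / "proteins.fasta")
        write_tsv(bundle.mapping, out / "mapping.tsv")
        write_tsv(bundle.markers, out / "markers.tsv")
        write_tsv(bundle.truth, out / "truth.tsv")
        write_protein_fasta([("reference", bundle.reference)],
                            out / "reference.fasta")
        for name in ("proteins.fasta", "mapping.tsv", "markers.tsv",
                     "truth.tsv", "reference.fasta"):
            record("synth", out / name)
    elif kind == "rates":
        enzymes = _load_enzymes(section)
        enzyme = enzymes[section.get("enzyme", next(iter(enzymes)))]
        branch = enzyme.nad if section.get("cofactor", "NAD") == "NAD" else enzyme.nadp
        spec = SynthKineticsSpec(
            true_branch=branch,
            noise_cv=float(section.get("noise_cv", 0.05)),
            replicates=int(section.get("replicates", 1)),
            seed=seed, enzyme_name=enzyme.name)
        dataset, truth = gen_rate_dataset(spec)
        write_rate_dataset(dataset, out / "rates.tsv")
        write_tsv(truth, out / "truth.tsv")
        record("synth", out / "rates.tsv")
        record("synth", out / "truth.tsv")
    else:
        raise ValidationError(f"unknown synth kind {kind!r}")


_STAGE_FUNCS = {"phi": _stage_phi, "simulate": _stage_simulate,
                "fit": _stage_fit, "selwyn": _stage_selwyn,
                "classify": _stage_classify, "synth": _stage_synth}


def report(manifest: dict, base_dir=".") -> str:
    """Human-readable markdown summary of a run manifest.

    Missing outputs are listed as absent; checksum mismatches are flagged as
    integrity failures.  Neither is fatal.
    """
    base = Path(base_dir)
    lines = [f"# g6pdhkit run report", "",
             f"Package version: {manifest.get('version', '?')}; "
             f"seed: {manifest.get('seed', '?')}", ""]
    lines.append("## Stages")
    for stage, status in manifest.get("stages", {}).items():
        lines.append(f"- {stage}: {status}")
    lines.append("")
    lines.append("## Outputs")
    for entry in manifest.get("outputs", []):
        path = Path(entry["path"])
        if not path.is_absolute():
            path = base / path
        if not path.exists():
            lines.append(f"- {entry['path']} (stage {entry['stage']}): ABSENT")
            continue
        ok = _sha256(path) == entry["sha256"]
        flag = "ok" if ok else "INTEGRITY FAILURE (checksum mismatch)"
        lines.append(f"- {entry['path']} (stage {entry['stage']}): {flag}")
        if path.name == "phi.tsv" and ok:
            df = pd.read_csv(path, sep="\t")
            lines.append("")
            lines.append("### Cofactor specificity constants")
            for _, row in df.iterrows():
                lines.append(f"  - {row['enzyme']}: phi = {row['phi']:.4g}")
            lines.append("")
        elif path.name == "fit.json" and ok:
            fit = json.loads(path.read_text())
            lines.append("")
            lines.append("### Fit estimates")
            for name, value in fit.get("estimates", {}).items():
                ci = fit.get("ci95", {}).get(name)
                ci_txt = f" (95% CI {ci[0]:.4g}-{ci[1]:.4g})" if ci else ""
                lines.append(f"  - {name}: {value:.4g}{ci_txt}")
            lines.append("")
        elif path.name == "enzyme_comparison.tsv" and ok:
            df = pd.read_csv(path, sep="\t")
            lines.append("")
            lines.append("### Simulated NADH:NADPH output")
            for _, row in df.iterrows():
                lines.append(f"  - {row['enzyme']}: median ratio "
                             f"{row['median_ratio']:.4g}, G6P sensitivity "
                             f"{row['g6p_sensitivity']:.4g}")
            lines.append("")
        elif path.name == "taxon_summary.tsv" and ok:
            df = pd.read_csv(path, sep="\t")
            lines.append("")
            lines.append("### Taxon partitions (sum check)")
            for (taxon, part), sub in df.groupby(["taxon", "partition"]):
                total = sub["fraction"].sum()
                lines.append(f"  - {taxon}/{part}: fractions sum to {total:.6f}")
            lines.append("")
    return "\n".join(lines)
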