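"""End-to-end orchestration from a single YAML config.

``run_pipeline`` validates the config up front (paths exist, thresholds in
range) and then runs the requested stages in dependency order, writing TSV
outputs plus a ``.prov.json`` provenance sidecar (config hash, seed, package
version) next to each one and a manifest of artefact checksums at the end.
Reruns with an identical config and inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    conservation_compare,
    delta_phylop,
    overlap_tfbs,
    read_bed,
    read_bedgraph,
)
from .cohort import (
    cluster_tumours,
    cox_fit,
    first_exon_fractions,
    km_logrank,
    stratify,
)
from .correlation import (
    delta_methylation,
    methylation_expression_correlation,
    site_correlation_matrix,
)
from .errors import ValidationError
from .methylation import (
    conversion_qc,
    epiallele_patterns,
    methylated_fraction,
    methylation_wide,
    parse_read_calls,
)
from .sites import read_site_table

STAGES = [
    "methylation", "patterns", "delta", "site_correlation",
    "expression_correlation", "tfbs", "conservation", "cohort",
]

_PARAM_RANGES = {
    "min_coverage": (0, 10_000),
    "top_k": (1, 10_000),
    "min_frequency": (0.0, 1.0),
    "presence_threshold": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "min_reads": (0, 10_000_000),
    "k_clusters": (2, 10_000),
}


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    config["_config_path"] = str(path)
    return config


def validate_config(config: dict) -> None:
    if config.get("schema_version") != 1:
        raise ValidationError(
            f"unsupported schema_version {config.get('schema_version')!r}"
        )
    for stage in config.get("stages", []):
        if stage not in STAGES:
            raise ValidationError(f"unknown stage {stage!r}")
    inputs = config.get("inputs", {})
    for name, path in inputs.items():
        if path is not None and not Path(path).exists():
            raise ValidationError(f"input {name!r}: no such file {path}")
    params = config.get("params", {})
    for key, (lo, hi) in _PARAM_RANGES.items():
        if key in params and not (lo <= params[key] <= hi):
            raise ValidationError(
                f"parameter {key}={params[key]} outside [{lo}, {hi}]"
            )
    required = {"sites", "reads"}
    missing = required - {k for k, v in inputs.items() if v}
    if missing:
        raise ValidationError(f"missing required inputs: {sorted(missing)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    clean = {k: v for k, v in config.items() if not k.startswith("_")}
    return hashlib.sha256(
        json.dumps(clean, sort_keys=True, default=str).encode()
    ).hexdigest()


class _Writer:
    def __init__(self, out_dir: Path, config: dict):
        self.out_dir = out_dir
        self.sidecar = {
            "config_hash": _config_hash(config),
            "seed": config.get("seed"),
            "promomethyl_version": __version__,
        }
        self.outputs: list[Path] = []

    def write(self, df: pd.DataFrame, name: str, index: bool = False) -> Path:
        path = self.out_dir / name
        df.to_csv(path, sep="\t", index=index)
        with open(path.with_suffix(path.suffix + ".prov.json"), "w") as fh:
            json.dump(self.sidecar, fh, indent=2, sort_keys=True)
        self.outputs.append(path)
        return path


def run_pipeline(config) -> dict:
    """Run the configured stages; return the artefact manifest.

    ``config`` is a dict or a path to a YAML file.  Validation failures
    raise before any stage runs; a stage failure halts the run with the
    failing stage named.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    validate_config(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = config["inputs"]
    params = config.get("params", {})
    stages = config.get("stages", STAGES)
    writer = _Writer(out_dir, config)

    sites = read_site_table(inputs["sites"])
    readset = parse_read_calls_from_config(inputs, sites)
    wide = None

    current = None
    try:
        for stage in [s for s in STAGES if s in stages]:
            current = stage
            if stage == "methylation":
                matrix = methylated_fraction(
                    readset, min_coverage=params.get("min_coverage", 1)
                )
                writer.write(matrix, "methylation_long.tsv")
                wide = methylation_wide(matrix)
                writer.write(wide, "methylation_wide.tsv", index=True)
                if readset.non_cpg_tallies is not None:
                    writer.write(conversion_qc(readset), "conversion_qc.tsv")
            elif stage == "patterns":
                frames = []
                combos = readset.reads[["region_id", "sample_id"]].drop_duplicates()
                for r in combos.sort_values(["region_id", "sample_id"]).itertuples():
                    pft = epiallele_patterns(
                        readset, r.region_id, r.sample_id,
                        top_k=params.get("top_k", 10),
                        min_frequency=params.get("min_frequency", 0.01),
                    )
                    t = pft.table.copy()
                    t.insert(0, "sample", r.sample_id)
                    t.insert(0, "region_id", r.region_id)
                    t["n_reads_used"] = pft.n_reads_used
                    t["n_reads_excluded"] = pft.n_reads_excluded
                    frames.append(t)
                writer.write(pd.concat(frames, ignore_index=True), "patterns.tsv")
            elif stage == "delta":
                pairs = [tuple(p) for p in params.get("pairs", [])]
                if pairs:
                    wide = _require_wide(wide, readset, params)
                    writer.write(delta_methylation(wide, pairs), "delta.tsv")
            elif stage == "site_correlation":
                wide = _require_wide(wide, readset, params)
                corr = site_correlation_matrix(wide)
                writer.write(corr, "site_correlation.tsv", index=True)
            elif stage == "expression_correlation":
                if inputs.get("expression"):
                    wide = _require_wide(wide, readset, params)
                    expr = pd.read_csv(inputs["expression"], sep="\t")
                    table = methylation_expression_correlation(
                        wide, expr, alpha=params.get("alpha", 0.05)
                    )
                    flat = table.copy()
                    flat["site"] = flat["site"].astype(str)
                    writer.write(flat, "methylation_expression_correlation.tsv")
                    writer.write(
                        pd.DataFrame([table.attrs]),
                        "correlation_summary.tsv",
                    )
            elif stage == "tfbs":
                if inputs.get("tfbs"):
                    tfbs = read_bed(inputs["tfbs"])
                    ann = overlap_tfbs(sites, tfbs)
                    writer.write(ann, "tfbs_overlap.tsv")
                    writer.write(
                        pd.DataFrame(
                            [{"n_sites": len(sites),
                              "n_sites_with_tfbs": ann.attrs["n_sites_with_tfbs"]}]
                        ),
                        "tfbs_summary.tsv",
                    )
            elif stage == "conservation":
                if inputs.get("conservation") and inputs.get("regions"):
                    track = read_bedgraph(inputs["conservation"])
                    regions = read_bed(inputs["regions"], extra_names=("region_id",))
                    cpgs = {
                        rid: g["pos"].tolist()
                        for rid, g in sites.groupby("region_id")
                    }
                    comp = conservation_compare(track, regions, cpgs)
                    dp = delta_phylop(track, regions, cpgs)
                    writer.write(
                        pd.DataFrame(
                            [
                                {"comparison": "raw_phylop",
                                 "statistic_w": comp["statistic_w"],
                                 "p_value": comp["p_value"],
                                 "n_cpg": comp["n_cpg"],
                                 "n_other": comp["n_other"]},
                                {"comparison": "delta_phylop",
                                 "statistic_w": dp["statistic_w"],
                                 "p_value": dp["p_value"],
                                 "n_cpg": dp["n_cpg"],
                                 "n_other": dp["n_other"]},
                            ]
                        ),
                        "conservation_tests.tsv",
                    )
                    writer.write(dp["cpg_delta"], "delta_phylop_cpg.tsv")
            elif stage == "cohort":
                if inputs.get("cohort"):
                    cohort = pd.read_csv(inputs["cohort"], sep="\t")
                    exon_cols = params.get("exon_columns")
                    fractions = first_exon_fractions(
                        cohort, exon_cols, min_reads=params.get("min_reads", 10)
                    )
                    writer.write(fractions, "fractions.tsv", index=True)
                    clusters = cluster_tumours(
                        fractions, k=params.get("k_clusters", 5),
                        seed=config.get("seed", 0),
                    )
                    writer.write(clusters, "clusters.tsv", index=True)
                    endpoint = params.get("endpoint", "os")
                    surv_rows, km_frames = [], []
                    for exon, cutoff in params.get("cutoffs", {}).items():
                        grp = stratify(fractions, exon, cutoff)
                        res = km_logrank(cohort, grp, endpoint=endpoint)
                        km = res.km_curves.copy()
                        km.insert(0, "exon", exon)
                        km_frames.append(km)
                        surv_rows.append(
                            {"exon": exon, "cutoff": cutoff,
                             "endpoint": endpoint,
                             "logrank_chi2": res.logrank_chi2,
                             "logrank_p": res.logrank_p}
                        )
                        cohort[f"{exon}_high"] = (
                            grp.reindex(cohort["tumour_id"]).to_numpy() == "high"
                        ).astype(int)
                    if km_frames:
                        writer.write(pd.concat(km_frames, ignore_index=True),
                                     "km_curves.tsv")
                        writer.write(pd.DataFrame(surv_rows), "logrank.tsv")
                        covs = [f"{e}_high" for e in params.get("cutoffs", {})]
                        sub = cohort[cohort["tumour_id"].isin(fractions.index)]
                        cox = cox_fit(sub, covs, endpoint=endpoint,
                                      mode="univariable")
                        writer.write(cox, "cox.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage {current!r} failed: {exc}") from exc

    manifest = {
        "config_hash": writer.sidecar["config_hash"],
        "seed": config.get("seed"),
        "promomethyl_version": __version__,
        "outputs": {
            p.name: _sha256(p) for p in sorted(writer.outputs)
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _require_wide(wide, readset, params):
    if wide is None:
        wide = methylation_wide(
            methylated_fraction(readset, min_coverage=params.get("min_coverage", 1))
        )
    return wide


def parse_read_calls_from_config(inputs: dict, sites):
    readset = parse_read_calls(inputs["reads"], sites, format="native_tsv")
    tally_path = inputs.get("non_cpg_tallies")
    if tally_path:
        readset.non_cpg_tallies = pd.read_csv(tally_path, sep="\t")
    return readset
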