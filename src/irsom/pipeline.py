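"""End-to-end orchestration: normalize -> (DE ||| SOM -> select -> enrich).

The pipeline mirrors the two-branch workflow of the study design: the
differential-expression branch tests the three condition contrasts
(ischemia vs pre-ischemia, reperfusion vs ischemia, reperfusion vs
pre-ischemia) on counts, while the clustering branch maps per-condition
median log2-TPM profiles onto a hexagonal SOM, selects condition-specific
modules into four clusters, and scores gene-set enrichment per cluster.
Every stage writes a diff-able TSV and the run ends with a JSON report of
inputs, parameters, seeds and row counts.  One global seed fans out to
per-stage seeds through :func:`numpy.random.SeedSequence`, so identical
configs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from irsom import diffexpr, enrich, io, normalize, select, som
from irsom.io import CONDITIONS, CountMatrix, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_COMPARISONS = [
    ("pre_ischemia", "ischemia"),
    ("ischemia", "reperfusion"),
    ("pre_ischemia", "reperfusion"),
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the diagnostic."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from a YAML key-value file."""

    design: str = "design.tsv"
    quant_dir: str | None = None
    counts_tsv: str | None = None
    tx2gene: str | None = None
    gmt: str | None = None
    outdir: str = "results"
    seed: int = 0
    # normalization
    min_log2: float = math.log2(3.0)
    filter_aggregation: str = "max"
    # SOM
    som_rows: int = 7
    som_cols: int = 7
    epochs_ordering: int = 100
    epochs_tuning: int = 50
    epochs_polish: int = 0
    radius_start: float = 3.0
    radius_end: float = 2.0
    som_init: str = "pca"
    som_input: str = "centered"  # cluster trajectory shape, not abundance
    # selection
    selection_threshold: float = 1.0
    literal_table1: bool = False
    module_mean_scale: str = "log2"
    # differential expression
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [tuple(c) for c in DEFAULT_COMPARISONS]
    )
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    paired: bool = False
    # enrichment
    alpha: float = 0.05
    universe: str = "measured"
    # diagnostics
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "comparisons" in raw:
            raw["comparisons"] = [tuple(c) for c in raw["comparisons"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["comparisons"] = [list(c) for c in self.comparisons]
        return out


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Fan one global seed out to named per-stage seeds (SeedSequence spawn)."""
    children = np.random.SeedSequence(global_seed).spawn(2)
    return {
        "som": int(children[0].generate_state(1)[0] % (2**31)),
        "simulate": int(children[1].generate_state(1)[0] % (2**31)),
    }


def load_counts(config: PipelineConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Read the design then the counts (quant.sf directory or plain TSV)."""
    design = io.read_design(config.design)
    if config.quant_dir:
        tables = []
        for sample in design["sample"]:
            path = Path(config.quant_dir) / sample / "quant.sf"
            if not path.exists():
                raise ValidationError(f"missing quantification file {path}")
            tables.append(io.read_quant_table(path, sample))
        matrix = io.build_count_matrix(tables)
    elif config.counts_tsv:
        matrix = io.read_count_matrix(config.counts_tsv)
    else:
        raise ValidationError("config must set quant_dir or counts_tsv")
    extra = set(matrix.sample_ids) - set(design["sample"])
    if extra:
        raise ValidationError(f"samples {sorted(extra)[:3]} not in the design table")
    return matrix, design


def stage_normalize(
    matrix: CountMatrix,
    design: pd.DataFrame,
    min_log2: float,
    aggregation: str = "max",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPM -> log2 -> condition medians -> filters.

    Returns (full profile table with a ``retained`` flag, retained subset).
    """
    tpm = normalize.compute_tpm(matrix)
    log2 = normalize.log2_tpm(tpm)
    profiles = normalize.condition_medians(
        log2, matrix.feature_ids, matrix.sample_ids, design
    )
    retained = normalize.filter_transcripts(profiles, min_log2, aggregation)
    keep = set(retained["transcript_id"])
    profiles = profiles.copy()
    profiles["retained"] = profiles["transcript_id"].isin(keep)
    return profiles, retained


def som_input_matrix(retained: pd.DataFrame, som_input: str) -> np.ndarray:
    """SOM feature matrix: raw condition medians or per-transcript centered.

    Centering (the default) clusters trajectory *shape*: it removes the
    between-transcript abundance scale, which otherwise dominates the
    Euclidean metric, while the downstream module summaries still use the
    raw profiles (so the selection rules keep their absolute TPM meaning).
    """
    data = retained[["p_med", "i_med", "r_med"]].to_numpy(dtype=float)
    if som_input == "centered":
        return data - data.mean(axis=1, keepdims=True)
    if som_input == "raw":
        return data
    raise ValidationError(f"unknown som_input {som_input!r} (use centered|raw)")


def stage_som(
    retained: pd.DataFrame,
    config: PipelineConfig,
    seed: int,
) -> tuple[som.HexSOM, dict[str, int]]:
    data = som_input_matrix(retained, config.som_input)
    model = som.HexSOM(
        rows=config.som_rows,
        cols=config.som_cols,
        epochs_ordering=config.epochs_ordering,
        epochs_tuning=config.epochs_tuning,
        epochs_polish=config.epochs_polish,
        radius_start=config.radius_start,
        radius_end=config.radius_end,
        init=config.som_init,
        random_state=seed,
    ).fit(data)
    assignment = som.assign_modules(model, data, list(retained["transcript_id"]))
    return model, assignment


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write the stage TSVs and a JSON run report.

    Aborts with :class:`PipelineError` naming the failing stage; partial
    outputs stay on disk next to a ``FAILED`` marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "FAILED"
    seeds = stage_seeds(config.seed)
    report: dict = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "input_hashes": {},
        "stages": {},
    }
    stage = "load"
    try:
        for label, path in (
            ("design", config.design),
            ("quant_dir", config.quant_dir),
            ("counts_tsv", config.counts_tsv),
            ("tx2gene", config.tx2gene),
            ("gmt", config.gmt),
        ):
            if path and Path(path).is_file():
                report["input_hashes"][label] = _sha256(path)
        matrix, design = load_counts(config)
        report["stages"]["load"] = {
            "n_features": len(matrix.feature_ids),
            "n_samples": len(matrix.sample_ids),
        }

        stage = "normalize"
        profiles, retained = stage_normalize(
            matrix, design, config.min_log2, config.filter_aggregation
        )
        io.write_table(profiles, outdir / "profiles.tsv")
        report["stages"]["normalize"] = {
            "n_input": len(profiles),
            "n_retained": len(retained),
        }
        if retained.empty:
            raise ValidationError(
                "no transcript passed the zero/low-signal filters; nothing to cluster"
            )

        stage = "diffexpr"
        de_matrix = matrix
        if config.tx2gene:
            de_matrix = normalize.aggregate_to_genes(
                matrix, io.read_tx2gene(config.tx2gene)
            )
        de_summary = {}
        for group_a, group_b in config.comparisons:
            results = diffexpr.nb_test(
                de_matrix, design, group_a, group_b, paired=config.paired
            )
            up, down = diffexpr.select_degs(
                results, config.lfc_threshold, config.p_threshold
            )
            name = f"de_{group_b}_vs_{group_a}.tsv"
            io.write_table(results, outdir / name)
            de_summary[f"{group_b}_vs_{group_a}"] = {
                "n_up": len(up), "n_down": len(down), "n_deg": len(up) + len(down),
            }
        report["stages"]["diffexpr"] = de_summary

        stage = "som"
        model, assignment = stage_som(retained, config, seeds["som"])
        codebook = pd.DataFrame(model.codebook_, columns=["p", "i", "r"])
        codebook.insert(0, "module_id", np.arange(1, model.n_modules + 1))
        io.write_table(codebook, outdir / "som_codebook.tsv")
        io.write_table(
            pd.DataFrame(sorted(assignment.items()), columns=["transcript_id", "module"]),
            outdir / "som_assignment.tsv",
        )
        umatrix = model.u_matrix()
        io.write_table(
            pd.DataFrame(
                [(i + 1, j + 1, d) for (i, j), d in sorted(umatrix.pair_values.items())],
                columns=["module_a", "module_b", "distance"],
            ),
            outdir / "umatrix.tsv",
        )
        sizes = model.module_sizes(som_input_matrix(retained, config.som_input))
        report["stages"]["som"] = {
            "n_modules": int(model.n_modules),
            "n_empty_modules": int((sizes == 0).sum()),
            "quantization_error": model.quantization_error_,
        }

        stage = "select"
        summaries = select.summarize_modules(
            assignment, retained, model.n_modules, config.module_mean_scale
        )
        io.write_table(summaries, outdir / "module_summaries.tsv")
        clusters = select.assemble_clusters(
            summaries, assignment, config.selection_threshold, config.literal_table1
        )
        cluster_rows = [
            (
                label,
                ",".join(map(str, sorted(c.module_ids))),
                len(c.module_ids),
                c.n_genes,
            )
            for label, c in clusters.items()
        ]
        io.write_table(
            pd.DataFrame(
                cluster_rows, columns=["cluster", "module_ids", "n_modules", "n_genes"]
            ),
            outdir / "clusters.tsv",
        )
        member_rows = [
            (label, tx)
            for label, c in clusters.items()
            for tx in sorted(c.transcript_ids)
        ]
        io.write_table(
            pd.DataFrame(member_rows, columns=["cluster", "transcript_id"]),
            outdir / "cluster_members.tsv",
        )
        io.write_table(
            select.cluster_trajectory_report(clusters, retained),
            outdir / "cluster_trajectories.tsv",
        )
        io.write_table(
            select.cluster_overlap_table(clusters), outdir / "cluster_overlaps.tsv"
        )
        report["stages"]["select"] = {
            "n_clusters": len(clusters),
            "cluster_sizes": {label: c.n_genes for label, c in clusters.items()},
            "cluster_modules": {
                label: sorted(c.module_ids) for label, c in clusters.items()
            },
        }

        if config.plots:
            stage = "plots"
            from irsom import plots as plots_mod

            plots_mod.hex_panel(model, sizes, outdir / "som_panel.png")
            trajectories = pd.read_csv(
                outdir / "cluster_trajectories.tsv", sep="\t"
            )
            if len(trajectories):
                plots_mod.trajectory_panel(
                    trajectories, outdir / "cluster_trajectories.png"
                )
            for group_a, group_b in config.comparisons:
                name = f"de_{group_b}_vs_{group_a}"
                plots_mod.volcano(
                    pd.read_csv(outdir / f"{name}.tsv", sep="\t"),
                    f"{group_b} vs {group_a}",
                    outdir / f"{name}.png",
                )

        if config.gmt:
            stage = "enrich"
            sets = io.read_gmt(config.gmt)
            universe = _build_universe(config.universe, retained, sets)
            tables = enrich.enrich_clusters(clusters, sets, universe, config.alpha)
            enrich_summary = {}
            for label, frame in tables.items():
                io.write_table(frame, outdir / f"enrichment_{label}.tsv")
                enrich_summary[label] = {
                    "n_enriched": int(frame["enriched"].sum()),
                    "top_set": frame.iloc[0]["set_name"] if len(frame) else None,
                    "top_adj_p": float(frame.iloc[0]["adj_p"]) if len(frame) else None,
                }
            report["stages"]["enrich"] = enrich_summary
    except Exception as exc:
        marker.write_text(f"stage {stage}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    if marker.exists():
        marker.unlink()
    with open(outdir / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return report


def _build_universe(
    policy: str, retained: pd.DataFrame, sets: list[io.GeneSet]
) -> set[str]:
    if policy == "measured":
        return set(retained["transcript_id"])
    if policy == "collection":
        out: set[str] = set()
        for gs in sets:
            out |= gs.members
        return out
    raise ValidationError(f"unknown universe policy {policy!r} (use measured|collection)")


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()
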