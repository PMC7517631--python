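"""Synthetic RNA-seq data with planted condition trajectories and gene sets.

Emulates the study design every stage of the pipeline expects: 5 patients
biopsied at pre-ischemia, ischemia and reperfusion (15 samples), transcript
counts drawn negative-binomially (variance = mu + dispersion * mu^2) around
expected abundances that follow planted per-class condition multipliers,
with a multiplicative log-normal patient effect shared across a patient's
three samples.  Gene-set collections with one planted (truly enriched) set
per non-flat class plus uniform decoy sets exercise the enrichment stage,
and :func:`evaluate_recovery` scores how well the pipeline's clusters
recover the planted classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from irsom.io import (
    CONDITIONS,
    CountMatrix,
    GeneSet,
    QuantTable,
    ValidationError,
    write_design,
    write_gmt,
    write_quant_table,
    write_table,
)
from irsom.normalize import compute_tpm
from irsom.select import ClusterDefinition

#: Planted trajectory class -> the cluster expected to recover it.
CLASS_TO_CLUSTER = {
    "ischemia_up": "C1_ischemia_up",
    "ischemia_down": "C2_ischemia_down",
    "reperfusion_up": "C3_reperfusion_up",
    "reperfusion_down": "C4_reperfusion_down",
}


@dataclass
class TrajectoryClass:
    """A planted expression trajectory: condition multipliers on baseline.

    ``multipliers`` are (pre-ischemia, ischemia, reperfusion) factors;
    ``(1, 1, 1)`` is the flat background class.  The non-flat defaults are
    chosen to satisfy their selection rule with 4-fold / 2-fold margins on
    expectation.
    """

    name: str
    multipliers: tuple[float, float, float]
    n_transcripts: int

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0:
            raise ValidationError(f"class {self.name!r} has no transcripts")
        if any(m <= 0 for m in self.multipliers):
            raise ValidationError(f"class {self.name!r} multipliers must be positive")


@dataclass
class SimTruth:
    """Ground truth of a simulation: transcript classes and planted sets."""

    class_of: dict[str, str]
    planted_sets: dict[str, str] = field(default_factory=dict)

    def members(self, class_name: str) -> set[str]:
        return {t for t, c in self.class_of.items() if c == class_name}


def default_classes(n_per_class: int = 500, n_flat: int = 2000) -> list[TrajectoryClass]:
    """The study-condition class mix: 4-fold planted trajectories on a flat background.

    The non-flat multipliers are symmetric 4-fold patterns so that each
    class clears its selection rule with margin even after the compositional
    deflation TPM normalization introduces (planted up-regulation inflates a
    condition's library and shrinks everyone else's TPM there).
    """
    return [
        TrajectoryClass("flat", (1.0, 1.0, 1.0), n_flat),
        TrajectoryClass("ischemia_up", (1.0, 4.0, 4.0), n_per_class),
        TrajectoryClass("ischemia_down", (1.0, 0.25, 0.25), n_per_class),
        TrajectoryClass("reperfusion_up", (1.0, 1.0, 4.0), n_per_class),
        TrajectoryClass("reperfusion_down", (1.0, 1.0, 0.25), n_per_class),
    ]


def simulate_counts(
    classes: list[TrajectoryClass] | None = None,
    n_patients: int = 5,
    baseline_log2_mean: float = 8.0,
    baseline_log2_sd: float = 2.0,
    dispersion: float = 0.1,
    library_size: int = 2_000_000,
    efflen_range: tuple[float, float] = (200.0, 5000.0),
    patient_sd: float = 0.2,
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Draw a planted-trajectory count matrix plus its design table and truth.

    Per transcript a log-normal baseline abundance (log2 mean/sd as given)
    is multiplied per condition by the class multiplier and per patient by a
    shared log-normal effect (sd ``patient_sd`` in natural log units).
    Expected reads are allocated proportionally to abundance x effective
    length within each sample, scaled to ``library_size``, and observed
    counts are negative binomial (gamma-Poisson) with the given dispersion;
    ``dispersion = 0`` degenerates to Poisson.  Deterministic given ``seed``.
    """
    if classes is None:
        classes = default_classes()
    if not classes:
        raise ValidationError("need at least one trajectory class")
    rng = np.random.default_rng(seed)
    names: list[str] = []
    class_of: dict[str, str] = {}
    multipliers: list[tuple[float, float, float]] = []
    for cls in classes:
        for _ in range(cls.n_transcripts):
            tx = f"T{len(names) + 1:06d}"
            names.append(tx)
            class_of[tx] = cls.name
            multipliers.append(cls.multipliers)
    mult = np.asarray(multipliers)  # transcripts x 3 conditions
    n_tx = len(names)
    baseline = 2.0 ** rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_tx)
    efflen = rng.uniform(*efflen_range, size=n_tx)
    patient_effect = np.exp(rng.normal(0.0, patient_sd, size=(n_tx, n_patients)))
    sample_ids: list[str] = []
    design_rows = []
    counts = np.empty((n_tx, n_patients * len(CONDITIONS)))
    col = 0
    for p in range(n_patients):
        patient = f"P{p + 1}"
        for ci, condition in enumerate(CONDITIONS):
            sample = f"{patient}_{condition}"
            sample_ids.append(sample)
            design_rows.append((sample, patient, condition))
            abundance = baseline * mult[:, ci] * patient_effect[:, p]
            reads = abundance * efflen
            mu = reads / reads.sum() * library_size
            if dispersion > 0:
                lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
                counts[:, col] = rng.poisson(lam)
            else:
                counts[:, col] = rng.poisson(mu)
            col += 1
    matrix = CountMatrix(
        feature_ids=names,
        sample_ids=sample_ids,
        counts=counts,
        effective_lengths=efflen,
    )
    design = pd.DataFrame(design_rows, columns=["sample", "patient", "condition"])
    return matrix, design, SimTruth(class_of=class_of)


def simulate_genesets(
    truth: SimTruth,
    n_decoy_sets: int = 20,
    set_size_range: tuple[int, int] = (50, 200),
    planted_fraction: float = 0.8,
    seed: int = 0,
) -> list[GeneSet]:
    """One planted set per non-flat class plus uniform decoy sets.

    The planted set for class ``c`` holds ``planted_fraction`` of the class
    members plus random fillers up to the class size; decoys draw members
    uniformly from the whole transcript universe.  Updates
    ``truth.planted_sets`` in place and returns the collection.
    """
    if not 0 < planted_fraction <= 1:
        raise ValidationError("planted_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    universe = sorted(truth.class_of)
    sets: list[GeneSet] = []
    for class_name, cluster_label in CLASS_TO_CLUSTER.items():
        members = sorted(truth.members(class_name))
        if not members:
            continue
        n_planted = max(1, round(planted_fraction * len(members)))
        chosen = set(rng.choice(members, size=n_planted, replace=False))
        pool = [t for t in universe if t not in chosen]
        n_fill = len(members) - n_planted
        if n_fill > 0:
            chosen |= set(rng.choice(pool, size=n_fill, replace=False))
        name = f"planted_{class_name}"
        sets.append(GeneSet(name, f"planted set for {class_name}", frozenset(chosen)))
        truth.planted_sets[name] = cluster_label
    for d in range(n_decoy_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        members = frozenset(rng.choice(universe, size=min(size, len(universe)), replace=False))
        sets.append(GeneSet(f"decoy_{d + 1:03d}", "uniform decoy set", members))
    return sets


def evaluate_recovery(
    clusters: dict[str, ClusterDefinition],
    truth: SimTruth,
) -> pd.DataFrame:
    """Precision and recall of each cluster against its planted class.

    recall = |cluster ∩ planted| / |planted|; precision = |cluster ∩
    planted| / |cluster| (NaN for an empty cluster).  Flat transcripts
    inside a cluster count against its precision.
    """
    rows = []
    for class_name, label in CLASS_TO_CLUSTER.items():
        planted = truth.members(class_name)
        got = set(clusters[label].transcript_ids) if label in clusters else set()
        hit = len(got & planted)
        recall = hit / len(planted) if planted else np.nan
        precision = hit / len(got) if got else np.nan
        rows.append((class_name, label, len(planted), len(got), hit, recall, precision))
    return pd.DataFrame(
        rows,
        columns=["class", "cluster", "n_planted", "n_cluster", "n_recovered",
                 "recall", "precision"],
    )


def write_simulation(
    outdir: str | Path,
    matrix: CountMatrix,
    design: pd.DataFrame,
    truth: SimTruth,
    sets: list[GeneSet] | None = None,
) -> None:
    """Write per-sample quant.sf files, design.tsv, truth.tsv and sets.gmt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tpm = compute_tpm(matrix)
    efflen = matrix.efflen_matrix
    for j, sample in enumerate(matrix.sample_ids):
        sample_dir = outdir / sample
        sample_dir.mkdir(exist_ok=True)
        frame = pd.DataFrame(
            {
                "transcript_id": matrix.feature_ids,
                "length": np.round(efflen[:, j]) + 100,
                "effective_length": efflen[:, j],
                "tpm": tpm[:, j],
                "num_reads": matrix.counts[:, j],
            }
        )
        write_quant_table(QuantTable(sample, frame), sample_dir / "quant.sf")
    write_design(design, outdir / "design.tsv")
    truth_frame = pd.DataFrame(
        sorted(truth.class_of.items()), columns=["transcript_id", "class"]
    )
    write_table(truth_frame, outdir / "truth.tsv")
    if sets:
        write_gmt(sets, outdir / "sets.gmt")
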