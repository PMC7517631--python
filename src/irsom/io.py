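"""Readers and writers for the external formats the pipeline touches.

Formats: Salmon-style ``quant.sf`` tables (TSV with columns Name, Length,
EffectiveLength, TPM, NumReads), a sample design TSV (sample, patient,
condition), a two-column transcript-to-gene map, GMT gene-set collections,
and plain TSV count matrices.  All parsers validate strictly: identifiers
are opaque case-sensitive strings, row order is preserved, and malformed
input raises :class:`FormatError` naming the offending column/row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The three study conditions, in trajectory order.
CONDITIONS = ("pre_ischemia", "ischemia", "reperfusion")

#: Column order of the Salmon ``quant.sf`` dialect.
QUANT_COLUMNS = ("Name", "Length", "EffectiveLength", "TPM", "NumReads")

#: Float serialization used by every writer: 6 significant digits.
FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A parsed table violates a domain invariant."""


@dataclass
class QuantTable:
    """Per-sample transcript quantification (one Salmon-style file)."""

    sample_id: str
    frame: pd.DataFrame  # columns: transcript_id, length, effective_length, tpm, num_reads

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class GeneSet:
    """A named gene set from a GMT collection."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")


@dataclass
class CountMatrix:
    """Features x samples count matrix with per-feature effective lengths.

    ``effective_lengths`` may be a vector (one length per feature, shared by
    all samples) or a features x samples matrix (per-sample lengths as emitted
    by alignment-free quantifiers).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    effective_lengths: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.effective_lengths = np.asarray(self.effective_lengths, dtype=float)
        nf, ns = len(self.feature_ids), len(self.sample_ids)
        if self.counts.shape != (nf, ns):
            raise ValidationError(
                f"counts shape {self.counts.shape} != ({nf} features, {ns} samples)"
            )
        if self.effective_lengths.shape not in ((nf,), (nf, ns)):
            raise ValidationError(
                f"effective_lengths shape {self.effective_lengths.shape} "
                f"must be ({nf},) or ({nf}, {ns})"
            )
        if len(set(self.feature_ids)) != nf:
            raise ValidationError("duplicate feature identifiers in count matrix")
        if len(set(self.sample_ids)) != ns:
            raise ValidationError("duplicate sample identifiers in count matrix")
        if not np.all(np.isfinite(self.counts)) or (self.counts < 0).any():
            raise ValidationError("counts must be finite and non-negative")
        if not np.all(self.effective_lengths > 0):
            raise ValidationError("effective lengths must be positive")

    @property
    def efflen_matrix(self) -> np.ndarray:
        """Effective lengths broadcast to features x samples."""
        if self.effective_lengths.ndim == 1:
            return np.broadcast_to(
                self.effective_lengths[:, None], self.counts.shape
            )
        return self.effective_lengths


def read_quant_table(path: str | Path, sample_id: str) -> QuantTable:
    """Read one Salmon-style ``quant.sf`` file.

    Raises :class:`FormatError` on a missing column or non-numeric cell
    (with its row number) and :class:`ValidationError` on duplicate
    transcript identifiers or non-positive effective lengths.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in QUANT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    out = pd.DataFrame({"transcript_id": frame["Name"].astype(str)})
    for col, name in (
        ("Length", "length"),
        ("EffectiveLength", "effective_length"),
        ("TPM", "tpm"),
        ("NumReads", "num_reads"),
    ):
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.index[values.isna() & frame[col].notna()]
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric value {frame[col].iloc[bad[0]]!r} "
                f"in column {col}, data row {bad[0] + 1}"
            )
        if values.isna().any():
            row = int(values.index[values.isna()][0]) + 1
            raise FormatError(f"{path}: empty value in column {col}, data row {row}")
        out[name] = values.astype(float)
    dup = out["transcript_id"][out["transcript_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate transcript identifier {dup.iloc[0]!r}")
    if len(out) and not (out["effective_length"] > 0).all():
        raise ValidationError(f"{path}: effective lengths must be positive")
    if len(out) and not np.isfinite(out[["length", "effective_length", "tpm", "num_reads"]]).all().all():
        raise ValidationError(f"{path}: numeric fields must be finite")
    if len(out) and ((out["tpm"] < 0).any() or (out["num_reads"] < 0).any()):
        raise ValidationError(f"{path}: TPM and NumReads must be non-negative")
    return QuantTable(sample_id=sample_id, frame=out)


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    """Write a :class:`QuantTable` back in the ``quant.sf`` dialect."""
    out = pd.DataFrame(
        {
            "Name": table.frame["transcript_id"],
            "Length": table.frame["length"],
            "EffectiveLength": table.frame["effective_length"],
            "TPM": table.frame["tpm"],
            "NumReads": table.frame["num_reads"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the sample design table (columns: sample, patient, condition).

    Conditions are validated against ``pre_ischemia / ischemia / reperfusion``;
    sample ids and (patient, condition) pairs must be unique and every
    condition must occur at least once.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample", "patient", "condition") if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return validate_design(frame[["sample", "patient", "condition"]].copy(), source=str(path))


def validate_design(frame: pd.DataFrame, source: str = "design") -> pd.DataFrame:
    unknown = sorted(set(frame["condition"]) - set(CONDITIONS))
    if unknown:
        raise ValidationError(
            f"{source}: unknown condition(s) {unknown}; allowed: {list(CONDITIONS)}"
        )
    if frame["sample"].duplicated().any():
        dup = frame["sample"][frame["sample"].duplicated()].iloc[0]
        raise ValidationError(f"{source}: duplicate sample id {dup!r}")
    pairs = frame[["patient", "condition"]]
    if pairs.duplicated().any():
        dup = pairs[pairs.duplicated()].iloc[0]
        raise ValidationError(
            f"{source}: duplicate (patient, condition) pair "
            f"({dup['patient']!r}, {dup['condition']!r})"
        )
    absent = [c for c in CONDITIONS if c not in set(frame["condition"])]
    if absent:
        raise ValidationError(f"{source}: condition(s) {absent} have no samples")
    return frame.reset_index(drop=True)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT gene-set collection (name, description, members...)."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected name, description and at least one member"
                )
            name, description = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no members")
            if name in seen:
                raise ValidationError(f"{path}: duplicate set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name=name, description=description, members=members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as handle:
        for gs in sets:
            handle.write(
                "\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n"
            )


def read_tx2gene(path: str | Path, header: bool = False) -> dict[str, str]:
    """Read a two-column transcript-to-gene map.

    A transcript mapped to two different genes raises; an empty file returns
    an empty map with a warning.
    """
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            if header and lineno == 1:
                continue
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            tx, gene = fields[0], fields[1]
            if tx in mapping and mapping[tx] != gene:
                raise ValidationError(
                    f"{path}: transcript {tx!r} mapped to both {mapping[tx]!r} and {gene!r}"
                )
            mapping[tx] = gene
    if not mapping:
        logger.warning("%s: transcript-to-gene map is empty", path)
    return mapping


def build_count_matrix(tables: Sequence[QuantTable]) -> CountMatrix:
    """Join per-sample quant tables on transcript_id into a CountMatrix.

    Every sample must quantify the identical transcript universe; a
    transcript present in one sample but absent in another is an error
    (silent intersection would hide data loss).
    """
    if not tables:
        raise ValidationError("no quant tables given")
    ref_ids = list(tables[0].frame["transcript_id"])
    ref_set = set(ref_ids)
    for table in tables[1:]:
        ids = set(table.frame["transcript_id"])
        if ids != ref_set:
            only_ref = sorted(ref_set - ids)[:3]
            only_this = sorted(ids - ref_set)[:3]
            raise ValidationError(
                f"samples {tables[0].sample_id!r} and {table.sample_id!r} quantify "
                f"different transcript universes (e.g. {only_ref} vs {only_this})"
            )
    counts = np.empty((len(ref_ids), len(tables)))
    efflen = np.empty_like(counts)
    for j, table in enumerate(tables):
        frame = table.frame.set_index("transcript_id").loc[ref_ids]
        counts[:, j] = frame["num_reads"].to_numpy()
        efflen[:, j] = frame["effective_length"].to_numpy()
    return CountMatrix(
        feature_ids=ref_ids,
        sample_ids=[t.sample_id for t in tables],
        counts=counts,
        effective_lengths=efflen,
    )


def read_count_matrix(path: str | Path, efflens: Mapping[str, float] | None = None) -> CountMatrix:
    """Read a plain TSV count matrix (first column = feature id).

    Raw count TSVs carry no effective lengths; supply them via ``efflens``
    or every feature defaults to length 1 (TPM then reduces to counts per
    million).
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in frame.index]
    if efflens is None:
        lens = np.ones(len(ids))
    else:
        missing = [i for i in ids if i not in efflens]
        if missing:
            raise ValidationError(f"{path}: no effective length for {missing[:3]}")
        lens = np.array([float(efflens[i]) for i in ids])
    return CountMatrix(
        feature_ids=ids,
        sample_ids=[str(c) for c in frame.columns],
        counts=frame.to_numpy(dtype=float),
        effective_lengths=lens,
    )


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(
        matrix.counts, index=matrix.feature_ids, columns=matrix.sample_ids
    )
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Shared TSV writer: single header line, floats at 6 significant digits."""
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
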