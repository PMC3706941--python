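"""Core data model: sample-name codec, expression matrices, tabular I/O.

Samples follow the naming scheme ``<VINEYARD><YY><STAGE>[<REP>]``: a 2-3
letter uppercase vineyard code, a two-digit harvest-year token, a
developmental stage digit (1 = veraison, 2 = mid-ripening, 3 = harvest)
and an optional biological-replicate letter A-C.  ``FA081`` is vineyard FA,
year 2008, veraison, replicate-averaged; ``AM062B`` is replicate B.

Expression values are log2 fluorescence intensities (genes x samples).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleDescriptor",
    "ExpressionMatrix",
    "GeneSet",
    "SampleNameError",
    "MatrixLoadError",
    "parse_sample_name",
    "read_expression_table",
    "write_expression_table",
    "average_replicates",
    "normalize_to_veraison",
]

SCALE_TAGS = ("log2", "linear", "log2ratio")

_NAME_RE = re.compile(r"^([A-Z]+)(\d{2})(\d)([A-Z]?)$")


class SampleNameError(ValueError):
    """A sample name does not follow <VINEYARD><YY><STAGE>[<REP>]."""


class MatrixLoadError(ValueError):
    """An expression table violates the matrix invariants."""


@dataclass(frozen=True, order=True)
class SampleDescriptor:
    """Decoded sample identity: vineyard, harvest year, stage, replicate."""

    vineyard: str
    year: str
    stage: int
    replicate: str | None = None

    def __post_init__(self) -> None:
        if not (2 <= len(self.vineyard) <= 3) or not self.vineyard.isalpha() or not self.vineyard.isupper():
            raise SampleNameError(f"vineyard code {self.vineyard!r} must be 2-3 uppercase letters")
        if not (len(self.year) == 2 and self.year.isdigit()):
            raise SampleNameError(f"year token {self.year!r} must be two digits")
        if self.stage not in (1, 2, 3):
            raise SampleNameError(f"stage {self.stage!r} must be 1, 2 or 3")
        if self.replicate is not None and self.replicate not in ("A", "B", "C"):
            raise SampleNameError(f"replicate {self.replicate!r} must be A, B or C")

    @property
    def group(self) -> tuple[str, str, int]:
        """(vineyard, year, stage) — the replicate group key."""
        return (self.vineyard, self.year, self.stage)

    def encode(self) -> str:
        return f"{self.vineyard}{self.year}{self.stage}{self.replicate or ''}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.encode()


def parse_sample_name(name: str) -> SampleDescriptor:
    """Decode ``<VINEYARD><YY><STAGE>[<REP>]`` into a :class:`SampleDescriptor`.

    The vineyard token is the maximal leading alphabetic run.  Raises
    :class:`SampleNameError` naming the offending field on malformed input.
    """
    m = _NAME_RE.match(name)
    if m is None:
        # diagnose which field broke, for a useful message
        lead = re.match(r"^([A-Za-z]*)", name).group(1)
        rest = name[len(lead):]
        if not (2 <= len(lead) <= 3) or not lead.isupper():
            raise SampleNameError(f"{name!r}: vineyard code must be 2-3 uppercase letters")
        if len(rest) < 3 or not rest[:2].isdigit():
            raise SampleNameError(f"{name!r}: year token must be two digits")
        raise SampleNameError(f"{name!r}: trailing stage/replicate malformed")
    vineyard, year, stage_s, rep = m.groups()
    if not 2 <= len(vineyard) <= 3:
        raise SampleNameError(f"{name!r}: vineyard code must be 2-3 letters, got {vineyard!r}")
    stage = int(stage_s)
    if stage not in (1, 2, 3):
        raise SampleNameError(f"{name!r}: stage {stage} invalid (must be 1-3)")
    if rep and rep not in "ABC":
        raise SampleNameError(f"{name!r}: replicate {rep!r} invalid (must be A-C)")
    return SampleDescriptor(vineyard, year, stage, rep or None)


@dataclass
class ExpressionMatrix:
    """Genes x samples grid of log2 intensities with aligned identifiers.

    ``data`` is a pandas DataFrame indexed by gene id with one column per
    sample (column names are the encoded sample names).  ``samples`` holds
    the decoded descriptors in column order.
    """

    data: pd.DataFrame
    samples: list[SampleDescriptor]
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"scale_tag must be one of {SCALE_TAGS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise MatrixLoadError(f"duplicate gene ids: {dups}")
        if len(self.samples) != self.data.shape[1]:
            raise MatrixLoadError("sample descriptor count does not match column count")
        names = [s.encode() for s in self.samples]
        if len(set(names)) != len(names):
            raise MatrixLoadError("duplicate sample names")
        if list(self.data.columns) != names:
            self.data = self.data.set_axis(names, axis=1)
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise MatrixLoadError(
                f"non-finite value at gene {self.data.index[bad[0]]!r}, sample {names[bad[1]]!r}"
            )

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def vineyards(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.vineyard, None)
        return list(seen)

    def stages(self) -> list[int]:
        return sorted({s.stage for s in self.samples})

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [g for g in self.data.index if g in set(gene_ids)]
        return ExpressionMatrix(self.data.loc[ids].copy(), list(self.samples), self.scale_tag)

    def subset_samples(self, keep: Sequence[bool] | Sequence[int]) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return ExpressionMatrix(
            self.data.iloc[:, idx].copy(), [self.samples[i] for i in idx], self.scale_tag
        )

    def select(self, **fields: object) -> "ExpressionMatrix":
        """Subset samples by descriptor fields, e.g. ``select(stage=3, year="08")``."""
        mask = [all(getattr(s, k) == v for k, v in fields.items()) for s in self.samples]
        return self.subset_samples(mask)


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene identifiers."""

    label: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __and__(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(f"{self.label}&{other.label}", self.members & other.members)

    @classmethod
    def from_iterable(cls, label: str, genes: Iterable[str]) -> "GeneSet":
        return cls(label, frozenset(genes))


# ---------------------------------------------------------------------------
# I/O


def read_expression_table(
    path: str | Path,
    scale: str = "log2",
    annotation: str | Path | None = None,
) -> ExpressionMatrix:
    """Load a TSV expression table (first column gene ids, header sample names).

    With ``scale="linear"`` values are log2-transformed on load; non-positive
    linear values are a load error.  An optional sample-annotation TSV
    (columns: sample, vineyard, year, stage, replicate) overrides name parsing.
    """
    if scale not in SCALE_TAGS:
        raise ValueError(f"scale must be one of {SCALE_TAGS}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise MatrixLoadError(f"{path}: duplicate gene ids {dups}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()[:3]
            raise MatrixLoadError(f"{path}: non-numeric cells in column {col!r} at rows {bad}")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise MatrixLoadError(f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}")
    if annotation is not None:
        ann = pd.read_csv(annotation, sep="\t", dtype=str).set_index("sample")
        samples = [
            SampleDescriptor(
                ann.loc[c, "vineyard"],
                ann.loc[c, "year"],
                int(ann.loc[c, "stage"]),
                (None if pd.isna(ann.loc[c].get("replicate")) or ann.loc[c].get("replicate") in ("", None)
                 else str(ann.loc[c]["replicate"])),
            )
            for c in df.columns
        ]
    else:
        samples = [parse_sample_name(str(c)) for c in df.columns]
    if scale == "linear":
        vals = df.to_numpy(dtype=float)
        if (vals <= 0).any():
            r, c = np.argwhere(vals <= 0)[0]
            raise MatrixLoadError(
                f"{path}: non-positive linear value at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        df = pd.DataFrame(np.log2(vals), index=df.index, columns=df.columns)
        scale = "log2"
    return ExpressionMatrix(df.astype(float), samples, scale)


def write_expression_table(m: ExpressionMatrix, path: str | Path, sidecar: bool = True) -> None:
    """Write a TSV with identical layout plus a JSON sidecar recording scale."""
    path = Path(path)
    m.data.to_csv(path, sep="\t", float_format="%.10g")
    if sidecar:
        meta = {
            "scale_tag": m.scale_tag,
            "n_genes": m.n_genes,
            "n_samples": m.n_samples,
            "samples": m.sample_names,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# Replicate averaging and veraison normalization


def average_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse biological replicates to their arithmetic mean (log2 scale).

    Output has one column per (vineyard, year, stage) with the replicate
    field cleared; idempotent on already-averaged matrices.
    """
    groups: dict[tuple[str, str, int], list[int]] = {}
    for i, s in enumerate(m.samples):
        groups.setdefault(s.group, []).append(i)
    vals = m.values
    cols = {}
    descs = []
    for key, idx in groups.items():
        d = replace(m.samples[idx[0]], replicate=None)
        descs.append(d)
        cols[d.encode()] = vals[:, idx].mean(axis=1)
    df = pd.DataFrame(cols, index=m.data.index)
    return ExpressionMatrix(df, descs, m.scale_tag)


def normalize_to_veraison(m: ExpressionMatrix) -> ExpressionMatrix:
    """Express later stages relative to veraison (stage 1) per vineyard/year.

    Each stage-2/3 value becomes ``value - mean(stage-1 values of the same
    vineyard and year)``, a log2 ratio; stage-1 columns are dropped and the
    scale tag becomes ``log2ratio``.
    """
    baselines: dict[tuple[str, str], np.ndarray] = {}
    for vy in {(s.vineyard, s.year) for s in m.samples}:
        idx = [i for i, s in enumerate(m.samples) if (s.vineyard, s.year) == vy and s.stage == 1]
        if not idx:
            raise ValueError(f"no stage-1 (veraison) samples for vineyard {vy[0]}, year {vy[1]}")
        baselines[vy] = m.values[:, idx].mean(axis=1)
    keep = [i for i, s in enumerate(m.samples) if s.stage != 1]
    if not keep:
        raise ValueError("matrix has only stage-1 samples; nothing to normalize")
    cols = {}
    descs = []
    for i in keep:
        s = m.samples[i]
        descs.append(s)
        cols[s.encode()] = m.values[:, i] - baselines[(s.vineyard, s.year)]
    return ExpressionMatrix(pd.DataFrame(cols, index=m.data.index), descs, "log2ratio")
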