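"""Synthetic expression matrices with planted gene classes.

The generator emulates the multi-vineyard berry study design — by default
11 vineyards x 3 developmental stages x 3 biological replicates in one
season — and plants gene classes with known ground truth so the analysis
pipeline can be scored for parameter recovery:

``constitutive``    flat everywhere, tight replicate noise
``marker_up/down``  monotone +/- stage_effect per stage step, all vineyards
``plastic``         vineyard-specific intercepts, sd = plastic_effect_sd
``year_effect``     common per-year offsets
``bimodal_low``     baseline drawn from a two-point low-intensity mixture
                    (emulating the array's background/low-expression mode)
``background``      flat, ordinary replicate noise

All effects and noise are additive on the log2 scale (log-normal intensity
noise, the standard microarray assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core_data import ExpressionMatrix, SampleDescriptor

__all__ = ["SyntheticSpec", "TruthTable", "generate_dataset", "CLASS_LABELS"]

CLASS_LABELS = (
    "constitutive",
    "marker_up",
    "marker_down",
    "plastic",
    "year_effect",
    "bimodal_low",
    "background",
)

#: default per-class gene counts — 2,000 genes total, desk-scale
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "constitutive": 200,
    "marker_up": 100,
    "marker_down": 100,
    "plastic": 200,
    "year_effect": 100,
    "bimodal_low": 700,
    "background": 600,
}


@dataclass
class SyntheticSpec:
    """Design and effect-size parameters of a simulated experiment.

    Effect sizes are in log2 units.  ``baseline_mean``/``baseline_sd``
    describe the per-gene expression level distribution; ``bimodal_gap``
    separates the two low-intensity modes of the ``bimodal_low`` class.
    """

    n_vineyards: int = 11
    n_stages: int = 3
    n_replicates: int = 3
    n_years: int = 1
    class_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    baseline_mean: float = 10.0
    baseline_sd: float = 1.5
    stage_effect: float = 2.0
    plastic_effect_sd: float = 1.0
    plastic_stage_interaction: bool = False
    year_effect: float = 1.5
    replicate_noise_sd: float = 0.5
    bimodal_low_mean: float = 2.5
    bimodal_gap: float = 3.0
    constitutive_noise_sd: float | None = None  # default: replicate_noise_sd / 5
    seed: int = 0

    def validate(self) -> None:
        counts = dict(self.class_counts)
        unknown = set(counts) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if any(c < 0 for c in counts.values()):
            raise ValueError("class counts must be >= 0")
        if self.n_genes == 0:
            raise ValueError("zero total genes requested")
        if self.n_vineyards * self.n_stages * self.n_replicates * self.n_years == 0:
            raise ValueError("zero samples requested")
        if self.n_stages < 2 and (counts.get("marker_up", 0) or counts.get("marker_down", 0)):
            raise ValueError("markers require n_stages >= 2")
        for name in ("baseline_sd", "plastic_effect_sd", "replicate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.constitutive_noise_sd is not None and self.constitutive_noise_sd < 0:
            raise ValueError("constitutive_noise_sd must be >= 0")

    @property
    def constitutive_sd(self) -> float:
        """Replicate noise of constitutive genes (tighter than background)."""
        if self.constitutive_noise_sd is not None:
            return self.constitutive_noise_sd
        return self.replicate_noise_sd / 5.0

    @property
    def n_genes(self) -> int:
        return sum(self.class_counts.get(c, 0) for c in CLASS_LABELS)

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class TruthTable:
    """gene_id -> planted class label."""

    labels: dict[str, str]

    def genes_of(self, label: str) -> frozenset[str]:
        return frozenset(g for g, c in self.labels.items() if c == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": list(self.labels), "class": list(self.labels.values())})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TruthTable":
        return cls(dict(zip(df["gene_id"], df["class"])))


_VINEYARD_CODES = [
    "AM", "BA", "BM", "CC", "CS", "FA", "GIV", "MN", "PM", "PSP", "VM",
    "ZA", "ZB", "ZC", "ZD", "ZE", "ZF", "ZG", "ZH", "ZI", "ZL", "ZM",
]


def _vineyard_codes(n: int) -> list[str]:
    if n <= len(_VINEYARD_CODES):
        return _VINEYARD_CODES[:n]
    extra = [f"X{chr(65 + i // 26)}{chr(65 + i % 26)}"[:3] for i in range(n - len(_VINEYARD_CODES))]
    return _VINEYARD_CODES + extra


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionMatrix, TruthTable]:
    """Draw one full factorial dataset; identical seed gives identical output.

    value(g, v, y, t, r) = baseline_g
                         + stage term       (markers: +/- stage_effect * (t-1))
                         + vineyard offset  (plastic: per-vineyard N(0, plastic_effect_sd^2))
                         + year offset      (year_effect class: +/- year_effect / 2 alternating)
                         + replicate noise  N(0, replicate_noise_sd^2)
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    gene_ids: list[str] = []
    labels: list[str] = []
    for cls_name in CLASS_LABELS:
        n = spec.class_counts.get(cls_name, 0)
        for i in range(n):
            gene_ids.append(f"{cls_name}_{i:04d}")
            labels.append(cls_name)
    n_genes = len(gene_ids)
    lab = np.array(labels)

    # per-gene baselines
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_genes)
    is_bimodal = lab == "bimodal_low"
    n_bi = int(is_bimodal.sum())
    if n_bi:
        mode = rng.integers(0, 2, size=n_bi)  # balanced two-point mixture
        centers = spec.bimodal_low_mean + (mode - 0.5) * spec.bimodal_gap
        baseline[is_bimodal] = centers + rng.normal(0.0, 0.15, size=n_bi)

    # stage slopes
    slope = np.zeros(n_genes)
    slope[lab == "marker_up"] = spec.stage_effect
    slope[lab == "marker_down"] = -spec.stage_effect

    vineyards = _vineyard_codes(spec.n_vineyards)
    years = [f"{6 + y:02d}" for y in range(spec.n_years)]
    reps = "ABC"[: spec.n_replicates] if spec.n_replicates <= 3 else None
    if reps is None:
        raise ValueError("n_replicates must be <= 3 (replicate letters A-C)")

    # plastic vineyard offsets: genes x vineyards
    vin_offset = np.zeros((n_genes, spec.n_vineyards))
    is_plastic = lab == "plastic"
    vin_offset[is_plastic] = rng.normal(0.0, spec.plastic_effect_sd, size=(int(is_plastic.sum()), spec.n_vineyards))
    if spec.plastic_stage_interaction:
        vin_slope = np.zeros((n_genes, spec.n_vineyards))
        vin_slope[is_plastic] = rng.normal(0.0, spec.plastic_effect_sd / 2,
                                           size=(int(is_plastic.sum()), spec.n_vineyards))
    else:
        vin_slope = None

    # year offsets (alternating sign keeps the grand mean near baseline)
    yr_offset = np.zeros((n_genes, spec.n_years))
    is_year = lab == "year_effect"
    for y in range(spec.n_years):
        yr_offset[is_year, y] = spec.year_effect * (1 if y % 2 else -1) / 2 * (0 if spec.n_years == 1 else 1)
    if spec.n_years == 1:
        yr_offset[:] = 0.0

    noise_sd = np.full(n_genes, spec.replicate_noise_sd)
    noise_sd[lab == "constitutive"] = spec.constitutive_sd

    descs: list[SampleDescriptor] = []
    columns: list[np.ndarray] = []
    for y, year in enumerate(years):
        for v, vin in enumerate(vineyards):
            for t in range(1, spec.n_stages + 1):
                for r in range(spec.n_replicates):
                    mu = baseline + slope * (t - 1) + vin_offset[:, v] + yr_offset[:, y]
                    if vin_slope is not None:
                        mu = mu + vin_slope[:, v] * (t - 1)
                    col = mu + rng.normal(0.0, 1.0, size=n_genes) * noise_sd
                    descs.append(SampleDescriptor(vin, year, t, reps[r]))
                    columns.append(col)

    df = pd.DataFrame(
        np.column_stack(columns), index=pd.Index(gene_ids, name="gene_id"),
        columns=[d.encode() for d in descs],
    )
    return ExpressionMatrix(df, descs, "log2"), TruthTable(dict(zip(gene_ids, labels)))
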