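"""Synthetic two-channel fluorescence fields and qPCR Cq tables.

The study's raw micrographs are not available, so this module generates
fields with exactly known ground truth that reproduce the statistical
structure the analysis assumes: non-overlapping roughly circular nuclei
visible in a DAPI channel, a mixture of gamma-H2AX-negative (dim) and
-positive (bright) cells in the signal channel, a smooth uneven background,
and additive sensor noise.  Per-cell peak intensities are quantized to the
integer bit grid before rasterization, so the recorded ``true_peak_signal``
is exactly the brightest background-free pixel of that cell — the scoring
statistic's ground truth is exact, not approximate.

A companion generator produces qPCR Cq tables built as the inverse of the
delta-delta-Ct model: treated-condition Cq values are shifted down by the
configured true log2 fold change, so the downstream analysis should recover
the configured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .classify import PositivitySummary

__all__ = [
    "SimFieldParams",
    "SimExperimentParams",
    "SimQpcrParams",
    "CellTruth",
    "GroundTruth",
    "FluorImagePair",
    "generate_field",
    "generate_experiment",
    "generate_qpcr_table",
    "simulate_positivity_experiment",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "image_id",
    "dapi_path",
    "signal_path",
    "experiment",
    "arm",
    "treatment",
    "field",
]

# Default qPCR panel: the H2AX-phosphorylation network genes assayed in the
# co-stress study (ATM/ATR kinases down, PP4 phosphatase up, its inhibitor
# CCDC6 down under osmotic stress), normalized to 18S.
_DEFAULT_GENES = ("ATM", "ATR", "PP4", "CCDC6")
_DEFAULT_LOG2_FC = {"ATM": -0.5, "ATR": -0.4, "PP4": 0.8, "CCDC6": -1.5}
_DEFAULT_CQ_OFFSETS = {"ATM": 14.0, "ATR": 14.5, "PP4": 13.0, "CCDC6": 12.5}


@dataclass(frozen=True)
class SimFieldParams:
    """One field's geometry, intensity model and noise.

    Intensities are on the raw camera scale of the chosen bit depth.  The
    negative/positive signal means set the separation between gamma-H2AX-dim
    and -bright cells; the defaults separate them by many noise SDs, which is
    what a usable immunofluorescence stain looks like.
    """

    image_height: int = 1024
    image_width: int = 1024
    n_cells: int = 150
    nucleus_radius_mean: float = 8.0
    nucleus_radius_sd: float = 1.0
    min_center_separation: float = 24.0
    positive_fraction: float = 0.10
    neg_signal_mean: float = 30.0
    neg_signal_sd: float = 8.0
    pos_signal_mean: float = 180.0
    pos_signal_sd: float = 15.0
    dapi_mean: float = 120.0
    dapi_sd: float = 15.0
    background_level: float = 10.0
    background_gradient_amplitude: float = 6.0
    background_sinusoid_amplitude: float = 0.0
    noise_sd: float = 2.0
    poisson_noise: bool = False
    bit_depth: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if self.pos_signal_mean <= self.neg_signal_mean:
            raise ValueError("pos_signal_mean must exceed neg_signal_mean")
        if self.image_height < 8 or self.image_width < 8:
            raise ValueError("image must be at least 8x8")

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16


@dataclass(frozen=True)
class CellTruth:
    center: tuple[float, float]  # (row, col)
    radius: float
    is_positive: bool
    true_peak_signal: float


@dataclass(frozen=True)
class GroundTruth:
    cells: tuple[CellTruth, ...]
    true_positive_fraction: float

    def __len__(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class FluorImagePair:
    """One field: DAPI and signal channels plus its place in the layout."""

    dapi: np.ndarray
    signal: np.ndarray
    image_id: str = ""
    experiment: str = ""
    arm: str = ""
    treatment: str = ""
    field_index: int = 0


@dataclass(frozen=True)
class SimExperimentParams:
    """Layout of one simulated co-stress experiment.

    ``arm_effects`` maps (arm, treatment) to a multiplicative factor on the
    baseline positive fraction; untreated conditions must have factor 1.  The
    default factors follow the pattern of the co-stress readout: DNA-damage
    treatments raise positivity strongly in the control arm and much less
    after osmotic pre-stress.
    """

    experiment: str = "exp1"
    baseline_positive_fraction: float = 0.10
    arm_effects: dict = field(
        default_factory=lambda: {
            ("control", "untreated"): 1.0,
            ("control", "UV"): 2.4,
            ("control", "H2O2"): 4.7,
            ("osmotic", "untreated"): 1.0,
            ("osmotic", "UV"): 1.2,
            ("osmotic", "H2O2"): 1.9,
        }
    )
    n_fields_per_condition: int = 3
    field_params: SimFieldParams = field(default_factory=SimFieldParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fields_per_condition < 1:
            raise ValueError("n_fields_per_condition must be >= 1")
        for (arm, treatment), factor in self.arm_effects.items():
            if treatment == "untreated" and factor != 1.0:
                raise ValueError(
                    f"untreated condition ({arm}) must have factor 1, got {factor}"
                )

    def condition_fraction(self, arm: str, treatment: str) -> float:
        raw = self.baseline_positive_fraction * self.arm_effects[(arm, treatment)]
        if not 0.0 <= raw <= 1.0:
            warnings.warn(
                f"configured positive fraction {raw:.3f} for ({arm}, {treatment}) "
                "clamped to [0, 1]",
                stacklevel=2,
            )
        return float(np.clip(raw, 0.0, 1.0))


@dataclass(frozen=True)
class SimQpcrParams:
    genes: tuple = _DEFAULT_GENES
    true_log2_fc: dict = field(default_factory=lambda: dict(_DEFAULT_LOG2_FC))
    reference_gene: str = "18S"
    n_replicates: int = 3
    n_technical: int = 2
    cq_noise_sd: float = 0.15
    reference_cq_mean: float = 12.0
    target_cq_offsets: dict = field(default_factory=lambda: dict(_DEFAULT_CQ_OFFSETS))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_technical < 1:
            raise ValueError("n_technical must be >= 1")
        if self.true_log2_fc.get(self.reference_gene, 0.0) != 0.0:
            raise ValueError("reference gene must have true_log2_fc 0")
        missing = [g for g in self.genes if g not in self.true_log2_fc]
        if missing:
            raise ValueError(f"true_log2_fc missing genes: {missing}")
        missing = [g for g in self.genes if g not in self.target_cq_offsets]
        if missing:
            raise ValueError(f"target_cq_offsets missing genes: {missing}")


def _place_centers(params: SimFieldParams, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample cell centers with a minimum pairwise separation."""
    margin = params.nucleus_radius_mean + 3.0 * params.nucleus_radius_sd + 1.0
    lo_r, hi_r = margin, params.image_height - margin
    lo_c, hi_c = margin, params.image_width - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("image too small for the nucleus size")
    centers: list[tuple[float, float]] = []
    max_attempts = max(1000, 300 * params.n_cells)
    attempts = 0
    min_sq = params.min_center_separation**2
    while len(centers) < params.n_cells and attempts < max_attempts:
        attempts += 1
        cand = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
        if all(
            (cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_sq for r, c in centers
        ):
            centers.append(cand)
    if len(centers) < params.n_cells:
        raise ValueError(
            f"could not place {params.n_cells} cells with separation "
            f"{params.min_center_separation}: only {len(centers)} fit "
            f"in {params.image_height}x{params.image_width}"
        )
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def _paint_disks(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii: np.ndarray,
    values: np.ndarray,
) -> np.ndarray:
    """Rasterize uniform disks (center-in-pixel test), overlap resolved by max."""
    out = np.zeros(shape, dtype=float)
    for (cy, cx), rad, val in zip(centers, radii, values):
        r0 = max(0, int(np.floor(cy - rad)))
        r1 = min(shape[0], int(np.ceil(cy + rad)) + 1)
        c0 = max(0, int(np.floor(cx - rad)))
        c1 = min(shape[1], int(np.ceil(cx + rad)) + 1)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        inside = (rr - cy) ** 2 + (cc - cx) ** 2 <= rad**2
        patch = out[r0:r1, c0:c1]
        patch[inside] = np.maximum(patch[inside], val)
    return out


def _background(params: SimFieldParams) -> np.ndarray:
    h, w = params.image_height, params.image_width
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    bg = np.full((h, w), float(params.background_level))
    if params.background_gradient_amplitude:
        bg += params.background_gradient_amplitude * 0.5 * (
            rr / max(h - 1, 1) + cc / max(w - 1, 1)
        )
    if params.background_sinusoid_amplitude:
        bg += params.background_sinusoid_amplitude * (
            np.sin(2 * np.pi * rr / h) * np.sin(2 * np.pi * cc / w)
        )
    return bg


def generate_field(params: SimFieldParams) -> tuple[FluorImagePair, GroundTruth]:
    """Render one two-channel field and its exact ground truth.

    The signal channel carries, per cell, a uniform disk at 80% of the cell's
    peak value with a single brightest pixel at the (integer-quantized) peak
    value at the cell center; the DAPI channel carries a uniform disk per
    nucleus.  Both channels sit on a shared smooth background and receive
    independent additive Gaussian noise, then are rounded and clipped to the
    bit range.  The same seed reproduces the images bit for bit.
    """
    rng = np.random.default_rng(params.rng_seed)
    maxv = params.max_value
    centers = _place_centers(params, rng)
    n = params.n_cells
    radii = np.clip(
        rng.normal(params.nucleus_radius_mean, params.nucleus_radius_sd, n), 1.5, None
    )
    is_positive = rng.random(n) < params.positive_fraction
    peaks = np.where(
        is_positive,
        rng.normal(params.pos_signal_mean, params.pos_signal_sd, n),
        rng.normal(params.neg_signal_mean, params.neg_signal_sd, n),
    )
    peaks = np.rint(np.clip(peaks, 1.0, maxv))
    bodies = np.rint(0.8 * peaks)
    dapi_vals = np.rint(np.clip(rng.normal(params.dapi_mean, params.dapi_sd, n), 1.0, maxv))

    shape = (params.image_height, params.image_width)
    dapi = _paint_disks(shape, centers, radii, dapi_vals)
    signal = _paint_disks(shape, centers, radii, bodies)
    for (cy, cx), peak in zip(centers, peaks):
        py, px = int(round(cy)), int(round(cx))
        signal[py, px] = max(signal[py, px], peak)

    bg = _background(params)
    dapi += bg
    signal += bg
    if params.poisson_noise:
        dapi = rng.poisson(np.clip(dapi, 0, None)).astype(float)
        signal = rng.poisson(np.clip(signal, 0, None)).astype(float)
    if params.noise_sd > 0:
        dapi += rng.normal(0.0, params.noise_sd, shape)
        signal += rng.normal(0.0, params.noise_sd, shape)
    dapi = np.clip(np.rint(dapi), 0, maxv).astype(params.dtype)
    signal = np.clip(np.rint(signal), 0, maxv).astype(params.dtype)

    cells = tuple(
        CellTruth(
            center=(float(cy), float(cx)),
            radius=float(rad),
            is_positive=bool(pos),
            true_peak_signal=float(peak),
        )
        for (cy, cx), rad, pos, peak in zip(centers, radii, is_positive, peaks)
    )
    truth = GroundTruth(
        cells=cells,
        true_positive_fraction=float(is_positive.mean()) if n else 0.0,
    )
    return FluorImagePair(dapi=dapi, signal=signal), truth


def generate_experiment(
    params: SimExperimentParams, outdir: str | Path | None = None
) -> tuple[list[FluorImagePair], list[GroundTruth], pd.DataFrame]:
    """Generate every field of one experiment's arm x treatment layout.

    Conditions are iterated in sorted order and each field gets an
    independent child seed drawn from the experiment seed, so the whole
    layout is reproducible from ``params.rng_seed`` alone.  When ``outdir``
    is given, channels are written as single-channel TIFFs and the manifest
    and ground truth as CSVs; manifest paths are filled in accordingly.
    """
    rng = np.random.default_rng(params.rng_seed)
    images: list[FluorImagePair] = []
    truths: list[GroundTruth] = []
    rows = []
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for arm, treatment in sorted(params.arm_effects):
        frac = params.condition_fraction(arm, treatment)
        for fidx in range(params.n_fields_per_condition):
            child_seed = int(rng.integers(0, 2**31))
            fp = replace(
                params.field_params, positive_fraction=frac, rng_seed=child_seed
            )
            pair, truth = generate_field(fp)
            image_id = f"{params.experiment}_{arm}_{treatment}_f{fidx:02d}"
            pair = replace(
                pair,
                image_id=image_id,
                experiment=params.experiment,
                arm=arm,
                treatment=treatment,
                field_index=fidx,
            )
            dapi_path = signal_path = ""
            if out is not None:
                # paths are relative to the manifest so the tree is relocatable
                dapi_path = f"{image_id}_dapi.tif"
                signal_path = f"{image_id}_gh2ax.tif"
                tifffile.imwrite(out / dapi_path, pair.dapi)
                tifffile.imwrite(out / signal_path, pair.signal)
            images.append(pair)
            truths.append(truth)
            rows.append(
                {
                    "image_id": image_id,
                    "dapi_path": dapi_path,
                    "signal_path": signal_path,
                    "experiment": params.experiment,
                    "arm": arm,
                    "treatment": treatment,
                    "field": fidx,
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
        truth_rows = []
        for row, truth in zip(rows, truths):
            for ci, cell in enumerate(truth.cells):
                truth_rows.append(
                    {
                        "image_id": row["image_id"],
                        "cell_index": ci,
                        "row": cell.center[0],
                        "col": cell.center[1],
                        "radius": cell.radius,
                        "is_positive": cell.is_positive,
                        "true_peak_signal": cell.true_peak_signal,
                    }
                )
        pd.DataFrame(
            truth_rows,
            columns=[
                "image_id",
                "cell_index",
                "row",
                "col",
                "radius",
                "is_positive",
                "true_peak_signal",
            ],
        ).to_csv(out / "ground_truth.csv", index=False)
    return images, truths, manifest


def generate_qpcr_table(params: SimQpcrParams) -> pd.DataFrame:
    """Simulate a Cq table whose delta-delta-Ct analysis recovers the truth.

    For target gene g the treated-condition Cq is the control Cq minus the
    configured true log2 fold change (one extra template doubling removes one
    cycle), and the reference gene's Cq is condition-independent; Gaussian
    cycle noise is added per measurement.  Columns: sample_id, condition,
    gene, replicate, cq.
    """
    rng = np.random.default_rng(params.rng_seed)
    rows = []
    all_genes = (params.reference_gene, *params.genes)
    for condition in ("control", "treated"):
        for rep in range(1, params.n_replicates + 1):
            sample_id = f"{condition}_{rep}"
            for gene in all_genes:
                if gene == params.reference_gene:
                    base = params.reference_cq_mean
                else:
                    base = params.reference_cq_mean + params.target_cq_offsets[gene]
                    if condition == "treated":
                        base -= params.true_log2_fc[gene]
                for tech in range(1, params.n_technical + 1):
                    cq = base + rng.normal(0.0, params.cq_noise_sd)
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "condition": condition,
                            "gene": gene,
                            "replicate": tech,
                            "cq": float(cq),
                        }
                    )
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene", "replicate", "cq"])


def simulate_positivity_experiment(
    params: SimExperimentParams,
    n_cells_per_condition: int,
    rng: np.random.Generator,
    baseline_jitter_sd: float = 0.0,
) -> list[PositivitySummary]:
    """Draw per-condition positive-cell counts without rendering images.

    Cells are Bernoulli positives at the condition's configured fraction, so
    counts are binomial — the sampling distribution the imaging pipeline
    induces when intensity separation makes classification essentially
    error-free.  ``baseline_jitter_sd`` (log-normal sigma) perturbs the
    experiment's baseline to emulate the between-experiment baseline
    heterogeneity seen in replicate experiments; fold changes within an
    experiment are unaffected by the shared baseline.  Used for replicate-
    level power analysis where rendering hundreds of experiments would add
    nothing but runtime.
    """
    baseline = params.baseline_positive_fraction
    if baseline_jitter_sd > 0:
        baseline = float(
            np.clip(baseline * rng.lognormal(0.0, baseline_jitter_sd), 0.0, 1.0)
        )
    summaries = []
    for arm, treatment in sorted(params.arm_effects):
        frac = float(np.clip(baseline * params.arm_effects[(arm, treatment)], 0.0, 1.0))
        n_pos = int(rng.binomial(n_cells_per_condition, frac))
        summaries.append(
            PositivitySummary(
                experiment=params.experiment,
                arm=arm,
                treatment=treatment,
                n_cells=n_cells_per_condition,
                n_positive=n_pos,
            )
        )
    return summaries
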