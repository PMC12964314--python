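"""Segmentation evaluation metrics, agreement analyses and noise sweeps.

Six metrics compare a reference mask A with a test mask B: Dice overlap,
signed area difference AD = (|A| - |B|) x pixel area, relative absolute
area difference RAAD = 2 ||A| - |B|| / (|A| + |B|) x 100 (percent),
absolute diameter difference ADD, relative absolute diameter difference
RADD (also in percent), and the Hausdorff distance between the mask
boundaries.  The noise sweep measures how segmentation accuracy and the
rate of empty ("zero output") predictions degrade as the SNR drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import directed_hausdorff

from .phantom import add_noise
from .planimetry import boundary_points
from .segnet import dice_coefficient, predict

__all__ = [
    "MetricsReport", "SetSummary", "AgreementResult", "NoiseSweepResult",
    "compute_metrics", "hausdorff_distance", "evaluate_set", "agreement",
    "noise_sweep",
]


@dataclass
class MetricsReport:
    """All six metrics for one (reference, test) mask pair."""

    dice: float
    ad: float | None  # signed, mm^2
    raad: float | None  # percent
    add: float | None  # mm
    radd: float | None  # percent
    haus: float | None  # pixels (or mm when spacing applied)
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"dice": self.dice, "ad": self.ad, "raad": self.raad,
                "add": self.add, "radd": self.radd, "haus": self.haus,
                "flags": dict(self.flags)}


@dataclass
class AgreementResult:
    """Linear agreement between two measurement series.

    ``limits_of_agreement`` are the Bland-Altman limits
    mean(y - x) +/- 1.96 SD(y - x).
    """

    r_squared: float | None
    mean_difference: float
    limits_of_agreement: tuple[float, float]
    n: int


@dataclass
class NoiseSweepResult:
    """Mean Dice and zero-output rate per (noise model, SNR)."""

    snr_grid: list[float]
    noise_model: str
    mean_dice: list[float]
    zero_output_rate: list[float]
    seeds: list[int]


def hausdorff_distance(a: np.ndarray, b: np.ndarray,
                       spacing: float = 1.0) -> float:
    """Symmetric Hausdorff distance between two mask boundaries.

    Computed on the 4-neighbor boundary point sets with Euclidean
    pixel-center distances; ``spacing`` converts to mm for isotropic
    pixels.
    """
    pa = boundary_points(a)
    pb = boundary_points(b)
    d = max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])
    return float(d * spacing)


def compute_metrics(a: np.ndarray, b: np.ndarray,
                    diam_a: float | None = None,
                    diam_b: float | None = None,
                    pixel_spacing: tuple[float, float] = (1.0, 1.0),
                    haus_in_mm: bool = False) -> MetricsReport:
    """All six metrics between a reference mask A and a test mask B.

    Conventions for degenerate inputs: two empty masks give Dice 1
    (flagged); one empty mask gives Dice 0 with an undefined Hausdorff
    distance (flagged).  Diameter metrics are null unless both diameters
    are positive.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    sy, sx = pixel_spacing
    flags: dict = {}
    na, nb = int(a.sum()), int(b.sum())

    dice = dice_coefficient(a, b)
    if na == 0 and nb == 0:
        flags["both_empty"] = True
    elif na == 0 or nb == 0:
        flags["one_empty"] = True

    if na + nb > 0:
        ad = (na - nb) * sy * sx
        raad = 2.0 * abs(na - nb) / (na + nb) * 100.0
    else:
        ad = raad = None
    if diam_a is not None and diam_b is not None \
            and diam_a > 0 and diam_b > 0:
        add = abs(diam_a - diam_b)
        radd = 2.0 * abs(diam_a - diam_b) / (diam_a + diam_b) * 100.0
    else:
        add = radd = None
        if diam_a is not None or diam_b is not None:
            flags["diameter_undefined"] = True
    if na > 0 and nb > 0:
        haus = hausdorff_distance(a, b, spacing=sx if haus_in_mm else 1.0)
    else:
        haus = None
    return MetricsReport(dice=float(dice), ad=ad, raad=raad, add=add,
                         radd=radd, haus=haus, flags=flags)


_METRIC_FIELDS = ("dice", "ad", "raad", "add", "radd", "haus")


def evaluate_set(reports: list[MetricsReport]) -> dict:
    """Mean, SD and 95% CI per metric over a set of mask pairs.

    SD uses the n-1 denominator; the CI is the normal approximation
    mean +/- 1.96 SD / sqrt(n).  Pairs flagged as failures (an empty
    prediction) are excluded from the statistics and counted separately.
    """
    if not reports:
        raise ValueError("empty report list")
    failures = sum(1 for r in reports if "one_empty" in r.flags
                   or "both_empty" in r.flags)
    usable = [r for r in reports if "one_empty" not in r.flags
              and "both_empty" not in r.flags]
    summary: dict = {"n": len(usable), "n_failures": failures}
    for name in _METRIC_FIELDS:
        vals = np.array([getattr(r, name) for r in usable
                         if getattr(r, name) is not None], dtype=float)
        if vals.size == 0:
            summary[name] = {"mean": None, "sd": None, "ci95": None}
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else None
        ci = ((mean - 1.96 * sd / np.sqrt(vals.size),
               mean + 1.96 * sd / np.sqrt(vals.size))
              if sd is not None else None)
        summary[name] = {"mean": mean, "sd": sd, "ci95": ci}
    return summary


def agreement(x, y) -> AgreementResult:
    """OLS R-squared of y on x plus Bland-Altman agreement of y - x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1D series with n >= 3")
    if np.ptp(x) == 0:
        r2 = None
    else:
        r2 = float(stats.linregress(x, y).rvalue ** 2)
    d = y - x
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    loa = (mean_d - 1.96 * sd_d, mean_d + 1.96 * sd_d)
    return AgreementResult(r_squared=r2, mean_difference=mean_d,
                           limits_of_agreement=loa, n=int(x.size))


def noise_sweep(net, scenes, task: str, snr_grid, models=("gaussian",
                                                          "rician"),
                seed: int = 0, threshold: float = 0.5
                ) -> list[NoiseSweepResult]:
    """Segmentation robustness against noise at decreasing SNR.

    For each noise model and SNR, every scene image is corrupted, the
    network predicts a mask, and the Dice against the scene's ground
    truth for ``task`` is recorded; empty predictions count as failures
    with Dice 0.  Deterministic given ``seed``.
    """
    snr_grid = [float(s) for s in snr_grid]
    if not scenes or not snr_grid:
        raise ValueError("need at least one scene and one SNR")
    results = []
    ss = np.random.SeedSequence(seed)
    for model in models:
        dice_rows, zero_rows, used_seeds = [], [], []
        for snr in snr_grid:
            child = ss.spawn(1)[0]
            case_seeds = child.generate_state(len(scenes)) % (2 ** 31)
            dices, zeros = [], 0
            for scene, cseed in zip(scenes, case_seeds):
                noisy = add_noise(scene.image, model, snr, int(cseed))
                _, mask = predict(net, noisy, threshold=threshold)
                if not mask.any():
                    zeros += 1
                    dices.append(0.0)
                else:
                    dices.append(dice_coefficient(scene.masks[task], mask))
            dice_rows.append(float(np.mean(dices)))
            zero_rows.append(zeros / len(scenes))
            used_seeds.append(int(case_seeds[0]))
        results.append(NoiseSweepResult(
            snr_grid=snr_grid, noise_model=model, mean_dice=dice_rows,
            zero_output_rate=zero_rows, seeds=used_seeds))
    return results
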