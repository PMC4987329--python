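"""Agreement between the image-statistics classifier and the MVPA classifier.

If two binary classifiers label the same n images independently, one calling
``a`` of them "group members" and the other ``b``, the probability that they
agree on a random image is

    E = (a/n)(b/n) + (1 - a/n)(1 - b/n).

Observed agreement above this independence baseline indicates that the two
classifiers respond to shared underlying factors.  Each pole (the high- and
the low-rating group) is analyzed separately per participant, then a paired
one-tailed t-test across participants asks whether actual agreement exceeds
the expected baseline; the summary statistic averages the two poles.

The module also provides the per-subband two-sample t contrasts between
high- and low-rating groups (positive t = more energy in the high group) and
the exemplar-image lookup (most confidently, correctly classified image per
pole).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classification import CVResult
from .features import FeatureSet
from .grouping import PropertyGroups
from .pyramid import PyramidSpec

logger = logging.getLogger(__name__)

__all__ = [
    "AgreementResult",
    "SubbandContrast",
    "expected_agreement",
    "actual_agreement",
    "agreement_test",
    "subband_ttests",
    "exemplar_images",
    "plot_subband_contrast",
]


@dataclass
class AgreementResult:
    """Actual vs expected classifier agreement for one participant and pole."""

    property: str
    pole: str                  # "high" | "low"
    participant_id: str
    n: int                     # group size
    a: float                   # images labeled as the pole by classifier A
    b: float                   # ... by classifier B (may be a mean count)
    expected: float
    actual: float


@dataclass
class SubbandContrast:
    """Per-(scale, orientation) two-sample t values, high minus low."""

    property: str
    t_values: pd.DataFrame     # index = scale, columns = orientation
    n_high: int
    n_low: int


def expected_agreement(a: float, b: float, n: float) -> float:
    """Agreement probability of two independent binary classifiers.

    ``a`` and ``b`` are the counts (possibly participant-averaged, hence
    real-valued) of images each classifier labels as pole members out of
    ``n``.
    """
    if n <= 0:
        raise ValueError(f"group size must be positive, got {n}")
    if not (0 <= a <= n and 0 <= b <= n):
        raise ValueError(f"counts must lie in [0, {n}]; got a={a}, b={b}")
    pa, pb = a / n, b / n
    return pa * pb + (1.0 - pa) * (1.0 - pb)


def actual_agreement(labels_a: Sequence, labels_b: Sequence,
                     ids_a: Optional[Sequence[str]] = None,
                     ids_b: Optional[Sequence[str]] = None) -> float:
    """Fraction of images on which two classifiers give the same label.

    When image ids are provided, both label vectors are aligned on the
    common ordering and the image sets must match exactly.
    """
    la = np.asarray(labels_a)
    lb = np.asarray(labels_b)
    if ids_a is not None or ids_b is not None:
        if ids_a is None or ids_b is None:
            raise ValueError("provide ids for both classifiers or neither")
        sa, sb = pd.Series(la, index=ids_a), pd.Series(lb, index=ids_b)
        if set(sa.index) != set(sb.index):
            raise ValueError("mismatched image sets between classifiers")
        sb = sb.reindex(sa.index)
        la, lb = sa.to_numpy(), sb.to_numpy()
    if la.shape != lb.shape:
        raise ValueError(f"label vectors differ in length: {la.shape} vs {lb.shape}")
    return float(np.mean(la == lb))


def _one_tailed_paired_t(diffs: np.ndarray) -> Tuple[float, float]:
    if np.std(diffs, ddof=1) == 0:
        logger.warning("zero variance of agreement differences; degenerate p")
        if np.all(diffs == 0):
            return 0.0, 0.5
        return (np.inf, 0.0) if diffs[0] > 0 else (-np.inf, 1.0)
    res = sps.ttest_1samp(diffs, popmean=0.0, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def agreement_test(results: Sequence[AgreementResult]
                   ) -> Dict[str, Dict[str, float]]:
    """Paired one-tailed t-tests of (actual - expected) across participants.

    Returns per-pole statistics plus a pooled entry where each participant
    contributes the mean of their two pole differences (the summary-figure
    statistic).
    """
    df = pd.DataFrame([(r.pole, r.participant_id, r.actual - r.expected)
                       for r in results],
                      columns=["pole", "participant", "diff"])
    if df["participant"].nunique() < 2:
        raise ValueError("need results from at least 2 participants")
    out: Dict[str, Dict[str, float]] = {}
    for pole, sub in df.groupby("pole"):
        t, p = _one_tailed_paired_t(sub["diff"].to_numpy())
        out[pole] = {"t": t, "p": p, "mean_diff": float(sub["diff"].mean()),
                     "n_participants": int(len(sub))}
    pooled = df.groupby("participant")["diff"].mean().to_numpy()
    t, p = _one_tailed_paired_t(pooled)
    out["pooled"] = {"t": t, "p": p, "mean_diff": float(pooled.mean()),
                     "n_participants": int(len(pooled))}
    return out


def subband_ttests(spectra: FeatureSet | pd.DataFrame,
                   groups: PropertyGroups,
                   spec: PyramidSpec = PyramidSpec(6, 12)) -> SubbandContrast:
    """Two-sample t per (scale, orientation) subband energy, high minus low."""
    matrix = spectra.matrix if isinstance(spectra, FeatureSet) else spectra
    missing = [i for i in groups.all_ids if i not in matrix.index]
    if missing:
        raise ValueError(f"groups reference images missing from spectra: {missing[:5]}")
    if len(groups.high_ids) < 2 or len(groups.low_ids) < 2:
        raise ValueError("each group needs at least 2 images for a t-test")
    hi = matrix.loc[groups.high_ids]
    lo = matrix.loc[groups.low_ids]
    t = pd.DataFrame(index=pd.RangeIndex(1, spec.n_scales + 1, name="scale"),
                     columns=pd.RangeIndex(1, spec.n_orientations + 1,
                                           name="orientation"), dtype=float)
    for s in t.index:
        for o in t.columns:
            col = f"energy_s{s}_o{o}"
            res = sps.ttest_ind(hi[col], lo[col], equal_var=True)
            t.loc[s, o] = float(res.statistic)
    return SubbandContrast(property=groups.property, t_values=t,
                           n_high=len(hi), n_low=len(lo))


def exemplar_images(cv: CVResult, image_ids: Sequence[str],
                    groups: PropertyGroups) -> Dict[str, Optional[str]]:
    """Most confidently, correctly classified image per pole.

    Among the correctly classified images of each pole, the one with maximal
    posterior; ties resolve to the lowest image_id.  A pole with no correct
    classification yields None (with a warning).
    """
    lab = groups.labels()
    truth = np.array([lab.get(i) for i in image_ids], dtype=object)
    out: Dict[str, Optional[str]] = {}
    for pole in ("low", "high"):
        correct = [(image_ids[i], cv.posterior[i])
                   for i in range(len(image_ids))
                   if truth[i] == pole and cv.predicted[i] == pole]
        if not correct:
            logger.warning("no correctly classified image for pole %r", pole)
            out[pole] = None
            continue
        # max posterior; lowest id on ties
        correct.sort(key=lambda t: (-t[1], t[0]))
        out[pole] = correct[0][0]
    return out


def plot_subband_contrast(contrast: SubbandContrast, path) -> None:
    """Render the t grid as a heatmap (spatial frequency on the y axis)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = contrast.t_values.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    vmax = np.nanmax(np.abs(t)) or 1.0
    im = ax.imshow(t, cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   origin="upper", aspect="auto")
    ax.set_xlabel("orientation band")
    ax.set_ylabel("scale (fine → coarse)")
    ax.set_title(f"{contrast.property}: high - low subband energy (t)")
    fig.colorbar(im, ax=ax, label="t")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
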