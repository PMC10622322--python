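"""Quality control of peptide-spectrum matches.

Observed spectra are compared to predicted fragment spectra: peaks are
matched within a 10 ppm mass tolerance, observed intensities are scaled
so the observed median equals the predicted median, and the agreement
of the matched intensity vectors M = (m_1..m_n), P = (p_1..p_n) is
summarized as their angular similarity

    C(M, P) = sum(m_i p_i) / (sqrt(sum m_i^2) sqrt(sum p_i^2))
    A(M, P) = 1 - arccos(C(M, P)) / pi

which lies in [0.5, 1] for nonnegative intensities. Retention-time
agreement is the absolute difference of the centered/scaled observed
and predicted retention times, calibrated on confident PSMs. Confidence
is assessed by target-decoy competition: FDR at score s is the number
of decoys scoring >= s over the number of targets scoring >= s, and a
PSM's q-value is the running minimum of FDR from worst to best score.
PSMs with q-value below the threshold (default 1%) form the confident
subset, after removal of contaminant matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTAMINANT_PREFIX = "cont|"
DECOY_PREFIX = "decoy_"

# peak annotation categories (mirror-plot color scheme)
MATCHED = "matched"  # observed blue / predicted green
MISSING_PREDICTION = "missing_prediction"  # observed pink
UNMATCHED = "unmatched"  # observed gray / predicted red
UNANNOTATED = "unannotated"  # matched to a zero-intensity prediction


@dataclass(frozen=True)
class Spectrum:
    """A peak list with optional retention time and ion labels.

    m/z values (Th) must be strictly increasing; intensities are
    nonnegative, with NaN meaning "no intensity prediction" (allowed
    only in predicted spectra).
    """

    mz: np.ndarray
    intensity: np.ndarray
    retention_time: float | None = None
    identifier: str = ""
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(inten < 0):
                raise ValueError("intensities must be nonnegative")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class MatchedPeakVectors:
    """Intensities of matched observed (M) and predicted (P) peaks."""

    M: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        P = np.asarray(self.P, dtype=float)
        if M.shape != P.shape:
            raise ValueError("M and P must have equal length")
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "P", P)

    @property
    def n(self) -> int:
        return int(self.M.size)


@dataclass(frozen=True)
class PeakAnnotations:
    """Per-peak annotation categories for observed and predicted peaks."""

    observed: tuple[str, ...]
    predicted: tuple[str, ...]
    pairs: tuple[tuple[int, int], ...] = field(default=())  # (obs idx, pred idx)


def match_peaks(
    observed: Spectrum,
    predicted: Spectrum,
    tolerance_ppm: float = 10.0,
) -> tuple[MatchedPeakVectors, PeakAnnotations]:
    """Greedy one-to-one peak matching at a ppm tolerance.

    A pair qualifies when |mz_obs - mz_pred| / mz_pred <= tolerance in
    ppm (the prediction is the hypothesis under test, hence the
    denominator). Pairs are assigned in order of ascending ppm
    difference, ties broken by lower predicted m/z. Observed peaks
    matched to a prediction with missing (NaN) intensity are annotated
    ``missing_prediction`` and excluded from the M/P vectors. An empty
    observed spectrum yields an empty (n = 0) result.
    """
    obs_mz = observed.mz
    pred_mz = predicted.mz
    candidates: list[tuple[float, float, int, int]] = []
    for j, pmz in enumerate(pred_mz):
        tol = tolerance_ppm * 1e-6 * pmz
        lo = np.searchsorted(obs_mz, pmz - tol, side="left")
        hi = np.searchsorted(obs_mz, pmz + tol, side="right")
        for i in range(int(lo), int(hi)):
            ppm = abs(obs_mz[i] - pmz) / pmz * 1e6
            candidates.append((ppm, pmz, i, j))
    candidates.sort()
    obs_used = [False] * len(observed)
    pred_used = [False] * len(predicted)
    pairs: list[tuple[int, int]] = []
    for _, _, i, j in candidates:
        if obs_used[i] or pred_used[j]:
            continue
        obs_used[i] = True
        pred_used[j] = True
        pairs.append((i, j))
    pairs.sort()
    obs_cat = [UNMATCHED] * len(observed)
    pred_cat = [UNMATCHED] * len(predicted)
    m_vals: list[float] = []
    p_vals: list[float] = []
    for i, j in pairs:
        p_int = predicted.intensity[j]
        pred_cat[j] = MATCHED
        if np.isnan(p_int):
            obs_cat[i] = MISSING_PREDICTION
            continue
        obs_cat[i] = MATCHED
        m_vals.append(float(observed.intensity[i]))
        p_vals.append(float(p_int))
    return (
        MatchedPeakVectors(np.array(m_vals), np.array(p_vals)),
        PeakAnnotations(tuple(obs_cat), tuple(pred_cat), tuple(pairs)),
    )


def scale_observed(observed: Spectrum, predicted: Spectrum) -> Spectrum:
    """Scale observed intensities to match the predicted median intensity."""
    pred_int = predicted.intensity[~np.isnan(predicted.intensity)]
    if len(observed) == 0 or pred_int.size == 0:
        raise ValueError("both spectra need at least one peak with intensity")
    pred_median = float(np.median(pred_int))
    obs_median = float(np.median(observed.intensity))
    if obs_median == 0.0:
        obs_median = float(np.mean(observed.intensity))  # fall back to mean
        if obs_median == 0.0:
            raise ValueError("observed spectrum has zero median and mean intensity")
    factor = pred_median / obs_median
    return Spectrum(
        mz=observed.mz,
        intensity=observed.intensity * factor,
        retention_time=observed.retention_time,
        identifier=observed.identifier,
        labels=observed.labels,
    )


def angular_similarity(vectors: MatchedPeakVectors) -> float:
    """Angular similarity A(M, P) of the matched intensity vectors.

    Returns NaN (missing, not zero) when no peaks were matched.
    Undefined when either vector is all-zero.
    """
    if vectors.n == 0:
        return float("nan")
    m, p = vectors.M, vectors.P
    nm, np_ = float(np.linalg.norm(m)), float(np.linalg.norm(p))
    if nm == 0.0 or np_ == 0.0:
        raise ValueError("angular similarity undefined for all-zero vectors")
    # arccos(cosine) computed via the numerically stable arctan form, which
    # is exact for proportional vectors where arccos loses ~sqrt(eps)
    u, v = m / nm, p / np_
    angle = 2.0 * np.arctan2(np.linalg.norm(u - v), np.linalg.norm(u + v))
    return 1.0 - float(angle) / np.pi


def rt_deviation(
    observed_rt: np.ndarray,
    predicted_rt: np.ndarray,
    calibration_mask: np.ndarray,
) -> np.ndarray:
    """|z_observed - z_predicted| after calibration-set centering/scaling.

    Each series is centered by the calibration-set mean and scaled by
    its calibration-set standard deviation; confident PSMs (those
    passing the FDR threshold) form the calibration set.
    """
    observed_rt = np.asarray(observed_rt, dtype=float)
    predicted_rt = np.asarray(predicted_rt, dtype=float)
    mask = np.asarray(calibration_mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("calibration set needs at least 2 PSMs")
    zs = []
    for name, series in (("observed", observed_rt), ("predicted", predicted_rt)):
        cal = series[mask]
        sd = float(np.std(cal, ddof=1))
        if sd == 0.0:
            raise ValueError(f"zero variance in calibration {name} retention times")
        zs.append((series - float(np.mean(cal))) / sd)
    return np.abs(zs[0] - zs[1])


def _is_contaminant_match(accessions: str) -> bool:
    return any(
        part.startswith(CONTAMINANT_PREFIX)
        for part in str(accessions).split(";")
    )


def target_decoy_qvalues(
    psms: pd.DataFrame,
    threshold: float = 0.01,
    plus_one: bool = False,
    score_column: str = "score",
    label_column: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign target-decoy q-values and extract the confident subset.

    FDR at score s = (#decoys >= s) / (#targets >= s), optionally with
    the (#decoys + 1) correction; the q-value is the running minimum of
    FDR from worst to best score, capped at 1. The confident subset is
    targets with q-value strictly below ``threshold``; matches whose
    accessions include a contaminant record are then removed.
    Returns (all PSMs with a ``q_value`` column, confident subset).
    """
    if not (psms[label_column] == "target").any():
        raise ValueError("no target PSMs")
    df = psms.copy()
    order = np.argsort(-df[score_column].to_numpy(), kind="stable")
    scores = df[score_column].to_numpy()[order]
    is_decoy = (df[label_column].to_numpy() == "decoy")[order]
    cum_decoys = np.cumsum(is_decoy)
    cum_targets = np.cumsum(~is_decoy)
    numer = cum_decoys + (1 if plus_one else 0)
    with np.errstate(divide="ignore"):
        fdr = np.where(cum_targets > 0, numer / np.maximum(cum_targets, 1), np.inf)
    # at tied scores every PSM shares the FDR evaluated after the last tie
    n = len(scores)
    for i in range(n - 2, -1, -1):
        if scores[i] == scores[i + 1]:
            fdr[i] = fdr[i + 1]
    qvals = np.minimum(np.minimum.accumulate(fdr[::-1])[::-1], 1.0)
    q = np.empty(n)
    q[order] = qvals
    df["q_value"] = q
    confident = df[(df[label_column] == "target") & (df["q_value"] < threshold)]
    if "accessions" in confident.columns:
        confident = confident[
            ~confident["accessions"].map(_is_contaminant_match)
        ]
    return df, confident.copy()


def annotate_mirror(
    observed: Spectrum,
    predicted: Spectrum,
    annotations: PeakAnnotations,
) -> PeakAnnotations:
    """Final mirror-plot categories.

    Observed peaks: matched (blue), missing_prediction (pink) or
    unmatched (gray); predicted peaks: matched (green) or unmatched
    (red). A peak matching a fragment ion with a predicted intensity of
    exactly zero is left unannotated.
    """
    obs_cat = list(annotations.observed)
    pred_cat = list(annotations.predicted)
    for i, j in annotations.pairs:
        if predicted.intensity[j] == 0.0:
            obs_cat[i] = UNANNOTATED
            pred_cat[j] = UNANNOTATED
    return PeakAnnotations(tuple(obs_cat), tuple(pred_cat), annotations.pairs)


_OBS_COLORS = {
    MATCHED: "#1f77b4",  # blue
    MISSING_PREDICTION: "#e377c2",  # pink
    UNMATCHED: "#7f7f7f",  # gray
    UNANNOTATED: "#7f7f7f",
}
_PRED_COLORS = {
    MATCHED: "#2ca02c",  # green
    UNMATCHED: "#d62728",  # red
    UNANNOTATED: "#7f7f7f",
}


def plot_mirror(
    observed: Spectrum,
    predicted: Spectrum,
    annotations: PeakAnnotations,
    ax=None,
):
    """Mirror plot: observed on top, predicted mirrored below."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    final = annotate_mirror(observed, predicted, annotations)
    for i, (mz, inten) in enumerate(zip(observed.mz, observed.intensity)):
        ax.vlines(mz, 0, inten, color=_OBS_COLORS[final.observed[i]], lw=1)
    pred_int = np.nan_to_num(predicted.intensity, nan=0.0)
    for j, (mz, inten) in enumerate(zip(predicted.mz, pred_int)):
        ax.vlines(mz, 0, -inten, color=_PRED_COLORS[final.predicted[j]], lw=1)
        if predicted.labels is not None and inten > 0:
            ax.annotate(
                predicted.labels[j],
                (mz, -inten),
                fontsize=6,
                ha="center",
                va="top",
            )
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("m/z")
    ax.set_ylabel("intensity (observed / mirrored prediction)")
    return ax


def qc_table(
    psms: pd.DataFrame,
    angular: np.ndarray,
    rt_dev: np.ndarray,
) -> pd.DataFrame:
    """QC-augmented PSM table (q_value, angular_similarity, rt_deviation)."""
    out = psms.copy()
    out["angular_similarity"] = angular
    out["rt_deviation"] = rt_dev
    return out
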