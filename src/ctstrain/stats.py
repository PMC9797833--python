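"""ROC cutoff selection, wall-motion classification and evaluation
statistics.

A view is predicted abnormal when its longitudinal strain is *less
negative* than the cutoff (LS > tau; worse function means less
shortening), with equality counted abnormal — conservative toward
detection.  The optimal cutoff is the ROC operating point nearest the
upper-left corner (0, 1) in (1 - specificity, sensitivity) space, with
ties broken toward higher specificity; candidate thresholds are the
midpoints between consecutive sorted unique scores plus the two
infinities.  A study is abnormal if any of its views is abnormal.

Expert ground truth arrives as 16 AHA-segment labels (basal 1-6, mid
7-12, apical 13-16, no apical cap) from three readers; a segment is
consensus-abnormal when >= 2 readers call it non-normal (hypokinetic /
akinetic / dyskinetic pooled), a view when any mapped segment is
abnormal, a study when any view is.

Rates come with 95% Wald confidence intervals p +/- 1.96 sqrt(p(1-p)/n)
clipped to [0, 100]%.  Agreement uses Cohen's kappa (two raters) and
Fleiss's kappa (three readers); proportions are compared with a pooled
two-proportion z-test and R-squared values with Fisher's r-to-z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

NORMAL_LABEL = "normal"
ABNORMAL_LABELS = ("hypokinetic", "akinetic", "dyskinetic", "akinetic/dyskinetic")

#: default 16-segment AHA -> long-axis-view mapping (basal 1-6, mid 7-12,
#: apical 13-16; apical segments assigned to their wall's view).  Editable:
#: pass any {view: segment list} covering 1..16 instead.
DEFAULT_SEGMENT_VIEW_MAP = {
    "2CH": (1, 7, 13, 4, 10, 15),   # anterior + inferior walls
    "3CH": (2, 8, 5, 11),           # anteroseptal + inferolateral
    "4CH": (3, 9, 14, 6, 12, 16),   # septal + lateral
}

Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# expert-label consensus


def consensus_view_labels(labels: dict, segment_view_map: dict | None = None):
    """Binary consensus truth per view and per study.

    Parameters
    ----------
    labels : {reader: {segment(1..16): label string}} for one study.
    segment_view_map : {view: segments}; defaults to
        :data:`DEFAULT_SEGMENT_VIEW_MAP`.

    Returns
    -------
    (view_truth, study_truth) : ({view: bool}, bool)
    """
    seg_map = segment_view_map or DEFAULT_SEGMENT_VIEW_MAP
    readers = sorted(labels)
    if len(readers) < 2:
        raise ValueError("consensus needs at least 2 readers")
    gaps = [
        (r, s)
        for r in readers
        for s in range(1, 17)
        if s not in labels[r] or labels[r][s] is None
    ]
    if gaps:
        raise ValueError(f"missing reader/segment entries: {gaps}")
    seg_abnormal = {}
    for s in range(1, 17):
        votes = sum(
            1 for r in readers if str(labels[r][s]).lower() != NORMAL_LABEL
        )
        seg_abnormal[s] = votes >= 2
    view_truth = {
        v: any(seg_abnormal[s] for s in segs) for v, segs in seg_map.items()
    }
    return view_truth, any(view_truth.values())


# ---------------------------------------------------------------------------
# ROC and classification


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_threshold: float
    operating_point: tuple  # (sensitivity, specificity) at the optimum


def roc_and_optimal_cutoff(scores, truth) -> RocResult:
    """ROC over LS scores against binary truth; optimal tau nearest (0,1).

    Predicted abnormal iff score >= tau.  Thresholds are midpoints of
    consecutive sorted unique scores, bracketed by -inf and +inf.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("ROC needs both classes present in the truth")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, tau in enumerate(thresholds):
        pred = scores >= tau
        sens[i] = (pred & truth).sum() / n_pos
        spec[i] = (~pred & ~truth).sum() / n_neg
    # trapezoid over the ROC curve in (1-spec, sens); sort by fpr
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))
    d2 = fpr**2 + (1.0 - sens) ** 2
    best = np.flatnonzero(d2 == d2.min())
    best = best[np.argmax(spec[best])]  # tie -> higher specificity
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_threshold=float(thresholds[best]),
        operating_point=(float(sens[best]), float(spec[best])),
    )


def classify_view(ls: float, view: str, thresholds) -> bool:
    """Abnormal iff LS >= tau for the view (equality counts abnormal)."""
    if np.isscalar(thresholds):
        tau = float(thresholds)
    else:
        if view not in thresholds:
            raise ValueError(f"no threshold provided for view {view}")
        tau = float(thresholds[view])
    return bool(ls >= tau)


def classify_patient(view_classes) -> bool:
    """A study is abnormal if one or more of its views is abnormal."""
    view_classes = list(view_classes)
    if not view_classes:
        raise ValueError("study has no classified views")
    return any(view_classes)


# ---------------------------------------------------------------------------
# confusion metrics


def _wald_ci(p: float, n: int) -> tuple:
    half = Z95 * np.sqrt(p * (1.0 - p) / n)
    return (max(0.0, 100 * (p - half)), min(100.0, 100 * (p + half)))


@dataclass
class ClassMetrics:
    """Confusion counts and rates (percent) with 95% Wald CIs."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float = field(init=False)
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)
    ppv: float | None = field(init=False)
    ci: dict = field(init=False)

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        n = self.tp + self.fp + self.tn + self.fn
        if n < 1:
            raise ValueError("empty confusion table")
        self.ci = {}

        def rate(num, den, name):
            if den == 0:
                return None
            p = num / den
            self.ci[name] = _wald_ci(p, den)
            return 100.0 * p

        self.accuracy = rate(self.tp + self.tn, n, "accuracy")
        self.sensitivity = rate(self.tp, self.tp + self.fn, "sensitivity")
        self.specificity = rate(self.tn, self.tn + self.fp, "specificity")
        self.ppv = rate(self.tp, self.tp + self.fp, "ppv")

    def as_dict(self) -> dict:
        out = {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}
        for k in ("accuracy", "sensitivity", "specificity", "ppv"):
            v = getattr(self, k)
            out[k] = v
            if v is not None:
                out[f"{k}_ci"] = self.ci[k]
        return out


def confusion_metrics(pred, truth) -> ClassMetrics:
    """Confusion counts and rates from paired binary sequences."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    if len(pred) < 1:
        raise ValueError("need at least one case")
    return ClassMetrics(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )


# ---------------------------------------------------------------------------
# agreement


@dataclass
class AgreementResult:
    statistic: str  # "cohen" | "fleiss"
    kappa: float | None
    counts: np.ndarray


def cohen_kappa(a, b) -> AgreementResult:
    """Cohen's kappa between two label sequences."""
    from sklearn.metrics import cohen_kappa_score

    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    cats = np.unique(np.concatenate([a, b]))
    table = np.array(
        [[int(((a == x) & (b == y)).sum()) for y in cats] for x in cats]
    )
    if len(cats) < 2:
        return AgreementResult("cohen", None, table)  # p_e == 1, undefined
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        k = cohen_kappa_score(a, b)
    return AgreementResult("cohen", None if np.isnan(k) else float(k), table)


def fleiss_kappa(ratings) -> AgreementResult:
    """Fleiss's kappa for subjects x raters categorical ratings."""
    from statsmodels.stats.inter_rater import aggregate_raters
    from statsmodels.stats.inter_rater import fleiss_kappa as _fk

    ratings = np.asarray(ratings)
    if ratings.ndim != 2:
        raise ValueError("ratings must be 2D (subjects x raters)")
    table, _ = aggregate_raters(ratings)
    if ratings.shape[0] < 2 or table.shape[1] < 2:
        return AgreementResult("fleiss", None, table)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = _fk(table, method="fleiss")
    return AgreementResult("fleiss", None if np.isnan(k) else float(k), table)


# ---------------------------------------------------------------------------
# proportion / correlation comparison, linear fit


def two_prop_ztest(x1: int, n1: int, x2: int, n2: int) -> tuple:
    """Pooled two-proportion z statistic and two-tailed p-value."""
    if min(n1, n2) < 1 or not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("invalid counts")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("pooled proportion degenerate; z = 0", stacklevel=2)
        return 0.0, 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return float(z), float(2 * sps.norm.sf(abs(z)))


def compare_correlations(r1: float, r2: float, n1: int, n2: int) -> tuple:
    """Fisher r-to-z comparison of two correlation coefficients.

    Plain independent-samples Fisher transform; for correlations
    measured on the same sample this is an approximation (no
    dependent-sample adjustment is applied).
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    if min(n1, n2) <= 3:
        raise ValueError("need n > 3 per sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1 / (n1 - 3) + 1 / (n2 - 3)
    )
    return float(z), float(2 * sps.norm.sf(abs(z)))


@dataclass
class FitResult:
    slope: float
    intercept: float
    r2: float
    n: int
    band_x: np.ndarray  # abscissae of the confidence band
    band_lo: np.ndarray  # pointwise 95% CI of the mean fit
    band_hi: np.ndarray


def linfit_r2(x, y, n_band: int = 100) -> FitResult:
    """Least-squares line with R^2 and the 95% confidence band of the
    mean fit."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; fit undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    xs = np.linspace(x.min(), x.max(), n_band)
    pred = model.get_prediction(sm.add_constant(xs)).conf_int(alpha=0.05)
    return FitResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        n=len(x),
        band_x=xs,
        band_lo=pred[:, 0],
        band_hi=pred[:, 1],
    )
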