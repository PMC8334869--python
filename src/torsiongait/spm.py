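"""1-D statistical parametric mapping over gait-cycle fields.

Tests the association between a per-subject scalar (femoral torsion)
and 101-node gait-cycle curves with family-wise control by random
field theory:

* :class:`SPMRegression` - scalar field linear regression, SPM{t};
* :class:`SPMCanonicalCorrelation` - vector field CCA (the vectorial
  equivalent of linear regression), SPM{X2} with Bartlett's statistic
  X2 = -(n - 1 - (k + 2)/2) ln(1 - r^2) on a chi2(k) field;
* :class:`SPMPairedHotelling` - paired vector-field Hotelling T2,
  thresholded through the exact monotone map to an F field.

Each model's ``fit(alpha)`` returns an :class:`SPMResults` with the
statistic field, estimated smoothness, RFT critical threshold, and
suprathreshold clusters with RFT p-values. Post hoc per-component
scalar regressions use Bonferroni-adjusted levels alpha / k. Functional
wrappers (``regression_spm``, ``cca_spm``, ``hotelling_paired_spm``,
``posthoc_components``, ``report_filter``) mirror the class API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import rft
from .exceptions import SignalError

__all__ = [
    "SPMResults",
    "Cluster",
    "SPMRegression",
    "SPMCanonicalCorrelation",
    "SPMPairedHotelling",
    "regression_spm",
    "cca_spm",
    "hotelling_paired_spm",
    "posthoc_components",
    "report_filter",
    "estimate_fwhm",
    "smooth_gaussian_fields",
]

estimate_fwhm = rft.estimate_fwhm


@dataclass(frozen=True)
class Cluster:
    """One maximal suprathreshold run of the statistic field."""

    start: float  # %GC of first suprathreshold node
    end: float  # %GC of last suprathreshold node
    p_value: float

    @property
    def extent(self) -> float:
        """Cluster span in %GC (end - start)."""
        return self.end - self.start


@dataclass
class SPMResults:
    """Statistic field with its RFT inference."""

    stat_name: str  # "t" | "X2" | "T2"
    statistic_field: np.ndarray  # (101,)
    dof: tuple
    fwhm: float  # estimated smoothness, %GC (= nodes on the 1% grid)
    resels: float
    critical: float  # threshold at alpha (on the reported statistic scale)
    clusters: list  # list[Cluster]
    alpha: float
    two_tailed: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def has_suprathreshold(self) -> bool:
        return len(self.clusters) > 0

    def significant_nodes(self) -> np.ndarray:
        z = np.abs(self.statistic_field) if self.two_tailed else self.statistic_field
        return z > self.critical

    def summary(self) -> str:
        lines = [
            f"SPM{{{self.stat_name}}}  alpha={self.alpha:g}"
            + ("  (two-tailed)" if self.two_tailed else ""),
            f"  dof:      {self.dof}",
            f"  FWHM:     {self.fwhm:.2f} %GC   resels: {self.resels:.2f}",
            f"  critical: {self.stat_name}* = {self.critical:.3f}",
            f"  max |field|: {np.nanmax(np.abs(self.statistic_field)):.3f}",
        ]
        if self.clusters:
            lines.append("  clusters (%GC):")
            for c in self.clusters:
                lines.append(
                    f"    [{c.start:5.1f}, {c.end:5.1f}]  extent {c.extent:4.1f}"
                    f"  p = {c.p_value:.4f}"
                )
        else:
            lines.append("  no suprathreshold clusters")
        return "\n".join(lines)


def _find_clusters(z, u, stat, df, resels, fwhm, two_tailed):
    """Maximal runs of the (|.| if two-tailed) field above u."""
    zz = np.abs(z) if two_tailed else z
    above = zz > u
    clusters = []
    i = 0
    Q = len(zz)
    while i < Q:
        if above[i]:
            j = i
            while j + 1 < Q and above[j + 1]:
                j += 1
            extent_resels = (j - i) / fwhm
            p = rft.cluster_pvalue(u, extent_resels, stat, df, resels)
            if two_tailed:
                p = min(1.0, 2.0 * p)
            clusters.append(Cluster(start=float(i), end=float(j), p_value=p))
            i = j + 1
        else:
            i += 1
    return clusters


def _smoothness(residuals, n_nodes):
    """(fwhm, resels); constant residuals degrade to an infinitely smooth
    field whose family-wise threshold is the pointwise quantile."""
    try:
        fwhm = rft.estimate_fwhm(residuals)
    except SignalError:
        return np.inf, 0.0
    return fwhm, rft.resel_count(n_nodes, fwhm)


def _inference(z, stat, df, residuals, alpha, two_tailed, stat_name, meta=None):
    fwhm, resels = _smoothness(residuals, z.shape[0])
    a = alpha / 2.0 if two_tailed else alpha
    u = rft.critical_threshold(a, stat, df, resels)
    clusters = _find_clusters(z, u, stat, df, resels, fwhm, two_tailed)
    return SPMResults(
        stat_name=stat_name,
        statistic_field=z,
        dof=tuple(float(d) for d in np.atleast_1d(df)),
        fwhm=fwhm,
        resels=resels,
        critical=u,
        clusters=clusters,
        alpha=alpha,
        two_tailed=two_tailed,
        meta=meta or {},
    )


# ---------------------------------------------------------------------------
# scalar field regression
# ---------------------------------------------------------------------------

class SPMRegression:
    """Node-wise linear regression of a scalar field on a covariate.

    Parameters
    ----------
    field : (n, Q) array
        One curve per subject.
    x : (n,) array
        Per-subject scalar regressor (e.g. femoral torsion, deg).
    center : bool
        Centre the regressor (affects the intercept only).
    """

    def __init__(self, field, x, center: bool = True):
        Y = np.asarray(field, dtype=float)
        x = np.asarray(x, dtype=float)
        if Y.ndim != 2 or Y.shape[0] != x.shape[0]:
            raise ValueError("field must be (n, Q) matching len(x)")
        if Y.shape[0] < 3:
            raise ValueError("need at least 3 subjects")
        if np.std(x) == 0:
            raise ValueError("zero-variance regressor")
        self.y = Y
        self.x = x - x.mean() if center else x
        self.n, self.q = Y.shape

    def fit(self, alpha: float = 0.05, two_tailed: bool = True) -> SPMResults:
        x = self.x - self.x.mean()
        Yc = self.y - self.y.mean(axis=0)
        sxx = float(x @ x)
        beta = (x @ Yc) / sxx  # (Q,) slope
        resid = Yc - np.outer(x, beta)
        df = self.n - 2
        sse = (resid**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(sse / df / sxx)
            t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        t = np.where(np.isnan(t), 0.0, t)
        return _inference(
            t, "t", df, resid, alpha, two_tailed, "t",
            meta={"slope": beta, "n": self.n},
        )


# ---------------------------------------------------------------------------
# vector field CCA
# ---------------------------------------------------------------------------

class SPMCanonicalCorrelation:
    """Node-wise canonical correlation of a vector field with a scalar.

    With a single scalar regressor the first canonical correlation r at
    each node is the multiple correlation of x with the k components;
    the statistic field is Bartlett's X2 = -(n - 1 - (k + 2)/2)
    ln(1 - r^2), treated as a chi2(k) random field.
    """

    def __init__(self, fields, x, rank_policy: str = "error"):
        Y = np.asarray(fields, dtype=float)
        x = np.asarray(x, dtype=float)
        if Y.ndim != 3 or Y.shape[0] != x.shape[0]:
            raise ValueError("fields must be (n, Q, k) matching len(x)")
        n, q, k = Y.shape
        if n <= k + 2:
            raise ValueError(f"need n > k + 2 subjects (n={n}, k={k})")
        if np.std(x) == 0:
            raise ValueError("zero-variance regressor")
        if rank_policy not in ("error", "reduce"):
            raise ValueError("rank_policy must be 'error' or 'reduce'")
        self.y = Y
        self.x = x
        self.n, self.q, self.k = n, q, k
        self.rank_policy = rank_policy

    def canonical_r2(self) -> np.ndarray:
        """(Q,) squared first canonical correlation per node.

        A rank-deficient node-wise component covariance (e.g. a force
        component that is identically zero across subjects at a node)
        raises by default; with ``rank_policy='reduce'`` the correlation
        is evaluated on the non-degenerate subspace via the
        pseudo-inverse (degenerate components carry no information).
        """
        x = self.x - self.x.mean()
        Yc = self.y - self.y.mean(axis=0)
        sxx = float(x @ x)
        b = np.einsum("nqk,n->qk", Yc, x)  # (Q, k)
        S = np.einsum("nqk,nql->qkl", Yc, Yc)  # (Q, k, k)
        try:
            sol = np.linalg.solve(S, b[..., None])[..., 0]
        except np.linalg.LinAlgError as err:
            if self.rank_policy == "error":
                ranks = np.array(
                    [np.linalg.matrix_rank(S[i]) for i in range(self.q)]
                )
                bad = int(np.argmin(ranks))
                raise SignalError(
                    f"rank-deficient component covariance at node {bad}"
                ) from err
            sol = np.stack([np.linalg.pinv(S[i]) @ b[i] for i in range(self.q)])
        return np.einsum("qk,qk->q", b, sol) / sxx

    def fit(self, alpha: float = 0.05) -> SPMResults:
        n, k = self.n, self.k
        r2 = np.clip(self.canonical_r2(), 0.0, 1.0 - 1e-15)
        x2 = -(n - 1.0 - (k + 2.0) / 2.0) * np.log1p(-r2)
        # residuals of each component after regression on x, pooled
        x = self.x - self.x.mean()
        Yc = self.y - self.y.mean(axis=0)
        sxx = float(x @ x)
        beta = np.einsum("nqk,n->qk", Yc, x) / sxx
        resid = Yc - np.einsum("n,qk->nqk", x, beta)
        pooled = np.concatenate(
            [resid[:, :, j] for j in range(k)], axis=0
        )
        return _inference(
            x2, "chi2", k, pooled, alpha, False, "X2",
            meta={"r2": r2, "n": n, "k": k},
        )


# ---------------------------------------------------------------------------
# paired Hotelling T2
# ---------------------------------------------------------------------------

class SPMPairedHotelling:
    """Paired vector-field Hotelling T2 over the gait cycle.

    T2(q) = n dbar' S^-1 dbar on the paired differences; the RFT
    threshold comes from the exact monotone map to an
    F(k, n - k) field: F = T2 (n - k) / (k (n - 1)).
    """

    def __init__(self, fields_a, fields_b):
        A = np.asarray(fields_a, dtype=float)
        B = np.asarray(fields_b, dtype=float)
        if A.shape != B.shape:
            raise ValueError("paired field sets must have identical shapes")
        if A.ndim != 3:
            raise ValueError("fields must be (n, Q, k)")
        n, q, k = A.shape
        if n <= k:
            raise ValueError(f"need n > k pairs (n={n}, k={k})")
        self.d = A - B
        self.n, self.q, self.k = n, q, k

    def fit(self, alpha: float = 0.05) -> SPMResults:
        n, k = self.n, self.k
        dbar = self.d.mean(axis=0)  # (Q, k)
        Dc = self.d - dbar
        S = np.einsum("nqk,nql->qkl", Dc, Dc) / (n - 1)
        # pseudo-inverse with a range check: a mean difference outside the
        # column space of a singular covariance is a divergent T2
        t2 = np.empty(self.q)
        for q in range(self.q):
            sol = np.linalg.pinv(S[q]) @ dbar[q]
            resid = S[q] @ sol - dbar[q]
            scale_ref = max(1.0, float(np.abs(dbar[q]).max()))
            t2[q] = np.inf if np.abs(resid).max() > 1e-9 * scale_ref else (
                n * float(dbar[q] @ sol)
            )
        scale = (n - k) / (k * (n - 1.0))
        pooled = np.concatenate([Dc[:, :, j] for j in range(k)], axis=0)
        fwhm, resels = _smoothness(pooled, self.q)
        u_f = rft.critical_threshold(alpha, "F", (k, n - k), resels)
        u_t2 = u_f / scale
        clusters = _find_clusters(
            t2 * scale, u_f, "F", (k, n - k), resels, fwhm, False
        )
        return SPMResults(
            stat_name="T2",
            statistic_field=t2,
            dof=(k, n - k),
            fwhm=fwhm,
            resels=resels,
            critical=u_t2,
            clusters=clusters,
            alpha=alpha,
            meta={"n": n, "k": k, "f_scale": scale},
        )


# ---------------------------------------------------------------------------
# functional wrappers & reporting
# ---------------------------------------------------------------------------

def regression_spm(field, x, alpha: float = 0.05, two_tailed: bool = True) -> SPMResults:
    return SPMRegression(field, x).fit(alpha=alpha, two_tailed=two_tailed)


def cca_spm(fields, x, alpha: float = 0.05, rank_policy: str = "error") -> SPMResults:
    return SPMCanonicalCorrelation(fields, x, rank_policy=rank_policy).fit(alpha=alpha)


def hotelling_paired_spm(fields_a, fields_b, alpha: float = 0.05) -> SPMResults:
    return SPMPairedHotelling(fields_a, fields_b).fit(alpha=alpha)


def posthoc_components(fields, x, alpha: float = 0.05, two_tailed: bool = True) -> list:
    """Per-component scalar regressions at Bonferroni level alpha / k."""
    Y = np.asarray(fields, dtype=float)
    if Y.ndim == 2:
        Y = Y[:, :, None]
    k = Y.shape[2]
    return [
        regression_spm(Y[:, :, j], x, alpha=alpha / k, two_tailed=two_tailed)
        for j in range(k)
    ]


def report_filter(results, min_extent: float = 2.0):
    """Drop clusters whose %GC extent is <= ``min_extent``.

    Accepts one SPMResults or a list; returns the same structure with
    filtered cluster lists (fields and thresholds untouched).
    """
    if isinstance(results, SPMResults):
        kept = [c for c in results.clusters if c.extent > min_extent]
        out = SPMResults(
            stat_name=results.stat_name,
            statistic_field=results.statistic_field,
            dof=results.dof,
            fwhm=results.fwhm,
            resels=results.resels,
            critical=results.critical,
            clusters=kept,
            alpha=results.alpha,
            two_tailed=results.two_tailed,
            meta=dict(results.meta),
        )
        return out
    return [report_filter(r, min_extent) for r in results]


# ---------------------------------------------------------------------------
# smooth random fields (null simulations, calibration tests)
# ---------------------------------------------------------------------------

def smooth_gaussian_fields(rng, n: int, nodes: int = 101, k: int | None = None,
                           fwhm: float = 20.0) -> np.ndarray:
    """Unit-variance stationary Gaussian fields of known smoothness.

    White noise convolved with a Gaussian kernel of the requested FWHM
    (in nodes) and renormalized to unit variance; shape (n, nodes) or
    (n, nodes, k).
    """
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    pad = int(np.ceil(4 * sigma))
    shape = (n, nodes + 2 * pad) if k is None else (n, nodes + 2 * pad, k)
    white = rng.standard_normal(shape)
    off = np.arange(-pad, pad + 1)
    kernel = np.exp(-0.5 * (off / sigma) ** 2)
    kernel /= np.sqrt((kernel**2).sum())
    from scipy.signal import fftconvolve

    kshape = (1, len(kernel)) if k is None else (1, len(kernel), 1)
    sm = fftconvolve(white, kernel.reshape(kshape), mode="same", axes=1)
    out = sm[:, pad : pad + nodes] if pad else sm
    return out
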