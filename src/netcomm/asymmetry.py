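"""Send-receive asymmetry statistics.

The central object is a cohort tensor ``C`` of shape N×N×K, where
``C(i, j, k)`` is the communication efficiency (or coupling strength) from
node i to node j in subject k.  Asymmetry is assessed statistically across
the cohort:

* pairwise — a one-sample test of ``Δ(i, j, k) = C(i, j, k) − C(j, i, k)``
  against zero, yielding an antisymmetric matrix ``A`` of t (or signed-rank)
  statistics with Bonferroni control over the N(N−1)/2 distinct pairs;
* regional — the same test on ``δ(i, k) = S(i, k) − R(i, k)``, the gap
  between a node's mean outgoing and incoming efficiencies, with Bonferroni
  control over the N nodes; significantly positive nodes are classified as
  senders, significantly negative as receivers, the rest neutral.

For single directed networks (where no cohort exists) a normalized index
``A(i, j) = (E(i, j) − E(j, i)) / (E(i, j) + E(j, i))`` in [−1, 1] is used
instead, optionally restricted to node pairs without a direct structural
connection (directly connected pairs are trivially symmetric under
navigation-like measures).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .communication import CohortTensor
from .network import ValidationError, WeightedNetwork, partition_groups

__all__ = [
    "AsymmetryResult",
    "pairwise_asymmetry_test",
    "regional_asymmetry_test",
    "subsystem_downsample",
    "single_network_asymmetry",
    "regional_index",
    "asymmetry_correlation",
    "regress_out_covariate",
    "group_comparison_ranksum",
    "prepare_directed_tensor",
]


@dataclass
class AsymmetryResult:
    """Pairwise asymmetry statistics with multiplicity control.

    ``A`` is exactly antisymmetric (``A(i,j) = −A(j,i)``); ``p_raw`` and
    ``p_corrected`` are symmetric; ``sig`` marks pairs whose corrected
    p-value falls below ``alpha``.
    """

    A: np.ndarray
    p_raw: np.ndarray
    p_corrected: np.ndarray
    sig: np.ndarray
    alpha: float
    test: str
    correction: str
    labels: list[str] | None = None


def _one_sample_stat(delta: np.ndarray, test: str) -> tuple[float, float]:
    """Statistic and two-sided p for a one-sample location test against 0.

    ``test='t'``: Student t with K−1 df.  ``test='signed_rank'``: Wilcoxon
    signed-rank; the reported statistic is W+ − W− (sum of positive minus
    negative signed ranks) so that negating the sample negates the
    statistic.  Degenerate samples (zero variance) are handled explicitly:
    all-zero → (0, 1); constant nonzero → (±inf, 0).
    """
    d = np.asarray(delta, dtype=float)
    k = d.size
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        return (0.0, 1.0) if mean == 0 else (np.sign(mean) * np.inf, 0.0)
    if test == "t":
        t = mean / (sd / np.sqrt(k))
        p = 2.0 * stats.t.sf(abs(t), df=k - 1)
        return float(t), float(p)
    if test == "signed_rank":
        nz = d[d != 0]
        if nz.size == 0:
            return 0.0, 1.0
        ranks = stats.rankdata(np.abs(nz))
        w_signed = float((np.sign(nz) * ranks).sum())
        p = float(stats.wilcoxon(nz, alternative="two-sided").pvalue)
        return w_signed, p
    raise ValidationError(f"unknown test {test!r}; choose 't' or 'signed_rank'")


def _bonferroni(p: np.ndarray, m: int) -> np.ndarray:
    return np.minimum(1.0, p * m)


def pairwise_asymmetry_test(tensor: CohortTensor, alpha: float = 0.05,
                            test: str = "t",
                            correction: str = "bonferroni") -> AsymmetryResult:
    """Cohort-level test of directional preference for every node pair.

    For each unordered pair {i, j} the per-subject differences
    ``Δ(i, j, k) = C(i, j, k) − C(j, i, k)`` are tested against zero; the
    statistic is stored at (i, j) and its negation at (j, i).  A(i, j)
    significantly positive means communication is systematically more
    efficient from i to j than from j to i across the cohort.
    """
    if tensor.n_subjects < 2:
        raise ValidationError(
            "pairwise asymmetry test needs K >= 2 subjects; "
            "for a single directed network use single_network_asymmetry"
        )
    c = tensor.values
    n = tensor.n_nodes
    delta = c - c.transpose(1, 0, 2)
    A = np.zeros((n, n))
    p_raw = np.ones((n, n))
    iu, ju = np.triu_indices(n, k=1)
    if test == "t":
        d = delta[iu, ju, :]
        k = tensor.n_subjects
        mean = d.mean(axis=1)
        sd = d.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = mean / (sd / np.sqrt(k))
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=k - 1)
        degen = sd == 0
        with np.errstate(invalid="ignore"):
            tvals[degen] = np.where(mean[degen] == 0, 0.0,
                                    np.sign(mean[degen]) * np.inf)
        pvals[degen] = np.where(mean[degen] == 0, 1.0, 0.0)
    else:
        tvals = np.empty(iu.size)
        pvals = np.empty(iu.size)
        for idx in range(iu.size):
            tvals[idx], pvals[idx] = _one_sample_stat(delta[iu[idx], ju[idx], :], test)
    A[iu, ju] = tvals
    A[ju, iu] = -tvals
    p_raw[iu, ju] = pvals
    p_raw[ju, iu] = pvals
    m = n * (n - 1) // 2
    if correction == "bonferroni":
        p_corr = _bonferroni(p_raw, m)
    elif correction == "none":
        p_corr = p_raw.copy()
    else:
        raise ValidationError(f"unknown correction {correction!r}")
    np.fill_diagonal(p_corr, 1.0)
    np.fill_diagonal(p_raw, 1.0)
    sig = p_corr < alpha
    np.fill_diagonal(sig, False)
    return AsymmetryResult(A=A, p_raw=p_raw, p_corrected=p_corr, sig=sig,
                           alpha=alpha, test=test, correction=correction,
                           labels=tensor.labels)


def send_receive_efficiencies(tensor: CohortTensor) -> tuple[np.ndarray, np.ndarray]:
    """Per-node, per-subject mean send (S) and receive (R) efficiencies.

    The diagonal (self-pairs) is excluded, so means divide by N−1.
    """
    c = tensor.values
    n = tensor.n_nodes
    mask = ~np.eye(n, dtype=bool)
    S = np.einsum("ijk,ij->ik", c, mask) / (n - 1)
    R = np.einsum("ijk,ij->jk", c, mask) / (n - 1)
    return S, R


def regional_asymmetry_test(tensor: CohortTensor, alpha: float = 0.05,
                            test: str = "t",
                            correction: str = "bonferroni") -> pd.DataFrame:
    """Classify nodes as senders, receivers, or neutral.

    Tests ``δ(i, k) = S(i, k) − R(i, k)`` against zero per node with
    Bonferroni control over the N nodes.  The returned table carries the
    statistic ``a``, raw and corrected p-values, the role, and the
    regionally aggregated send/receive efficiencies ``s`` and ``r``
    (means across subjects; medians for navigation, whose failed-route
    zeros make means outlier-prone).
    """
    if tensor.n_subjects < 2:
        raise ValidationError(
            "regional asymmetry test needs K >= 2 subjects; "
            "for a single directed network use regional_index"
        )
    S, R = send_receive_efficiencies(tensor)
    delta = S - R
    n = tensor.n_nodes
    a = np.empty(n)
    p_raw = np.empty(n)
    for i in range(n):
        a[i], p_raw[i] = _one_sample_stat(delta[i], test)
    if correction == "bonferroni":
        p_corr = _bonferroni(p_raw, n)
    elif correction == "none":
        p_corr = p_raw.copy()
    else:
        raise ValidationError(f"unknown correction {correction!r}")
    sig = p_corr < alpha
    role = np.where(~sig, "neutral", np.where(a > 0, "sender", "receiver"))
    agg = np.median if tensor.measure == "nav" else np.mean
    s = agg(S, axis=1)
    r = agg(R, axis=1)
    labels = tensor.labels if tensor.labels is not None else [f"n{k}" for k in range(n)]
    df = pd.DataFrame(
        {"a": a, "p_raw": p_raw, "p_corrected": p_corr, "role": role,
         "s": s, "r": r},
        index=pd.Index(labels, name="node"),
    )
    return df


def subsystem_downsample(values: np.ndarray | CohortTensor,
                         partition: Mapping[str, str],
                         labels: Sequence[str] | None = None):
    """Average a node-level matrix (or tensor) into subsystem blocks.

    ``E'(u, v)`` is the mean of ``E(i, j)`` over i in subsystem u and j in
    subsystem v; for u = v the self-pairs i = j are excluded from the
    average.  Tensors are downsampled slice-wise.  Returns
    ``(downsampled, subsystem_labels)`` for arrays, or a new
    :class:`CohortTensor` for tensors.
    """
    if isinstance(values, CohortTensor):
        down, subs = subsystem_downsample(values.values, partition, labels=values.labels)
        return CohortTensor(down, subject_ids=list(values.subject_ids),
                            measure=values.measure, labels=subs,
                            provenance={**values.provenance, "downsampled": True})
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    if labels is None:
        labels = [f"n{k}" for k in range(n)]
    groups = partition_groups(partition, labels)
    subs = list(groups)
    m = len(subs)
    if m < 2:
        raise ValidationError("downsampling needs at least 2 subsystems")
    for name, idx in groups.items():
        if idx.size == 0:
            raise ValidationError(f"empty subsystem {name!r}")
    out_shape = (m, m) + v.shape[2:]
    out = np.zeros(out_shape)
    for a, u in enumerate(subs):
        for b, w in enumerate(subs):
            block = v[np.ix_(groups[u], groups[w])]
            if a == b:
                idx = groups[u]
                offdiag = ~np.eye(idx.size, dtype=bool)
                out[a, b] = block[offdiag].mean(axis=0) if idx.size > 1 else 0.0
            else:
                out[a, b] = block.mean(axis=(0, 1))
    return out, subs


def _admitted_mask(n: int, exclude_connected: bool,
                   net: WeightedNetwork | None) -> np.ndarray:
    mask = ~np.eye(n, dtype=bool)
    if exclude_connected:
        if net is None:
            raise ValidationError("exclude_connected requires the structural network")
        w = net.weights
        connected = (w > 0) | (w.T > 0)
        mask &= ~connected
    return mask


def single_network_asymmetry(E: np.ndarray, exclude_connected: bool = False,
                             net: WeightedNetwork | None = None) -> np.ndarray:
    """Normalized pairwise asymmetry index for one network, in [−1, 1].

    ``A(i, j) = (E(i, j) − E(j, i)) / (E(i, j) + E(j, i))``.  Pairs with a
    zero denominator, the diagonal, and (optionally) directly connected
    pairs are NaN.  Used where only a single (typically directed) network is
    available, so no cohort test applies.
    """
    e = np.asarray(E, dtype=float)
    n = e.shape[0]
    denom = e + e.T
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(denom != 0, (e - e.T) / denom, np.nan)
    mask = _admitted_mask(n, exclude_connected, net)
    a = np.where(mask, a, np.nan)
    return a


def regional_index(E: np.ndarray, exclude_connected: bool = False,
                   net: WeightedNetwork | None = None) -> np.ndarray:
    """Per-node normalized send-receive index over admitted pairs.

    ``(mean outgoing − mean incoming) / (mean outgoing + mean incoming)``
    per node; NaN for nodes with no admitted pairs or a zero denominator.
    """
    e = np.asarray(E, dtype=float)
    n = e.shape[0]
    mask = _admitted_mask(n, exclude_connected, net)
    out = np.full(n, np.nan)
    for i in range(n):
        adm = np.flatnonzero(mask[i])
        if adm.size == 0:
            continue
        send = e[i, adm].mean()
        recv = e[adm, i].mean()
        denom = send + recv
        if denom != 0:
            out[i] = (send - recv) / denom
    return out


def asymmetry_correlation(A1: np.ndarray, A2: np.ndarray,
                          sig_mask: np.ndarray | None = None) -> tuple[float, float, int]:
    """Pearson correlation of two asymmetry matrices' upper triangles.

    Non-finite entries (masked pairs) are dropped; ``sig_mask`` optionally
    restricts the comparison to pairs flagged significant in the first
    analysis.  Returns ``(r, p, n_pairs)``.
    """
    a1 = np.asarray(A1, dtype=float)
    a2 = np.asarray(A2, dtype=float)
    if a1.shape != a2.shape:
        raise ValidationError(f"shape mismatch {a1.shape} vs {a2.shape}")
    iu, ju = np.triu_indices(a1.shape[0], k=1)
    x, y = a1[iu, ju], a2[iu, ju]
    keep = np.isfinite(x) & np.isfinite(y)
    if sig_mask is not None:
        keep &= np.asarray(sig_mask, dtype=bool)[iu, ju]
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError(f"only {x.size} comparable pairs; need >= 3")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def regress_out_covariate(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of the OLS fit ``y ~ 1 + x`` (e.g., degree regressed out
    of a nodal asymmetry statistic)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("y and x must be equal-length vectors")
    if y.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValidationError("constant covariate: regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return np.asarray(model.resid)


def group_comparison_ranksum(values_a: Sequence[float],
                             values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two groups.

    Exact for small untied samples, normal approximation with tie
    correction otherwise (scipy's 'auto' policy).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def prepare_directed_tensor(matrices: Sequence[np.ndarray],
                            take_abs: bool = True,
                            subject_ids: Sequence[str] | None = None,
                            labels: Sequence[str] | None = None,
                            measure: str = "coupling") -> CohortTensor:
    """Stack K directed coupling matrices (e.g., effective connectivity)
    into a cohort tensor, taking entrywise absolute values by default
    (excitatory and inhibitory influences both reflect communication), and
    zeroing the diagonal."""
    mats = [np.asarray(m, dtype=float) for m in matrices]
    if not mats:
        raise ValidationError("no matrices given")
    shape = mats[0].shape
    if shape[0] != shape[1]:
        raise ValidationError(f"matrices must be square, got {shape}")
    for k, m in enumerate(mats):
        if m.shape != shape:
            raise ValidationError(f"matrix {k} has shape {m.shape}, expected {shape}")
    stack = np.stack(mats, axis=2)
    if take_abs:
        stack = np.abs(stack)
    idx = np.arange(shape[0])
    stack[idx, idx, :] = 0.0
    ids = list(subject_ids) if subject_ids is not None else [f"s{k}" for k in range(len(mats))]
    return CohortTensor(stack, subject_ids=ids, measure=measure,
                        labels=None if labels is None else list(labels))
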