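"""Detection calls, signed fold changes and per-side selection of changed genes.

The detection call follows the classic single-array scheme for
perfect-match/mismatch probe pairs: each pair's discrimination score
``R = (PM - MM) / (PM + MM)`` is tested against a small positive offset
``tau`` with a one-sided exact Wilcoxon signed-rank test (H1: median R >
tau).  The resulting p-value is thresholded into present / marginal /
absent.  Probe-set summarization itself (robust signal estimation,
background correction, between-array scaling) is out of scope: the
pipeline consumes already-summarized expression values, and the
probe-level stage is optional.

Fold changes are signed ratios of group means: ``+x`` means an x-fold
increase over the naive mean, ``-x`` an x-fold decrease; the codomain
excludes the open interval (-1, 1).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    CONTRA,
    IPSI,
    NAIVE,
    AnalysisConfig,
    ConfigError,
    ExpressionMatrix,
    InputError,
    normalize_symbol,
)

__all__ = [
    "DetectionCall",
    "discrimination_scores",
    "wilcoxon_signed_rank_right_p",
    "detection_call",
    "detection_calls_from_probes",
    "signed_fold_change",
    "select_changed_genes",
]

PRESENT, MARGINAL, ABSENT = "present", "marginal", "absent"

# exact enumeration of the signed-rank null is O(2^n); beyond this many
# probe pairs fall back to the normal approximation
_EXACT_LIMIT = 20


@dataclass(frozen=True)
class DetectionCall:
    gene: str
    sample: str
    call: str
    p_value: float


def discrimination_scores(pm, mm) -> np.ndarray:
    """Per-pair discrimination scores ``(PM - MM) / (PM + MM)``.

    Pairs with ``PM + MM == 0`` carry no signal and are excluded with a
    warning; if every pair is excluded the probe set is unscorable.
    """
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if pm.shape != mm.shape or pm.ndim != 1 or pm.size == 0:
        raise InputError("pm and mm must be equal-length non-empty vectors")
    if (pm < 0).any() or (mm < 0).any():
        raise InputError("probe intensities must be non-negative")
    total = pm + mm
    keep = total > 0
    if not keep.all():
        warnings.warn(f"excluded {int((~keep).sum())} zero-intensity probe pair(s)")
    if not keep.any():
        raise InputError("all probe pairs have zero total intensity")
    return (pm[keep] - mm[keep]) / total[keep]


def wilcoxon_signed_rank_right_p(diffs: np.ndarray) -> float:
    """Exact one-sided signed-rank p-value for H1: median(diffs) > 0.

    Zero differences are discarded (standard Wilcoxon treatment); ties
    among |differences| receive midranks.  The null distribution is
    enumerated exactly over all sign assignments for up to 20 pairs, and
    approximated by the tie-corrected normal beyond that.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all discrimination scores equal tau; degenerate call")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    if n <= _EXACT_LIMIT:
        # exact null: distribute W+ over all 2^n sign assignments by
        # polynomial convolution; midranks doubled to work in integers
        r2 = np.rint(2 * ranks).astype(int)
        dist = np.zeros(r2.sum() + 1, dtype=float)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: dist.size - r]
            dist = dist + shifted
        dist /= 2.0**n
        w2 = int(np.rint(2 * w_obs))
        return float(dist[w2:].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0  # tie correction
    z = (w_obs - 0.5 - mean) / math.sqrt(var)
    return float(stats.norm.sf(z))


def detection_call(scores, tau: float = 0.015, alpha1: float = 0.04,
                   alpha2: float = 0.06) -> tuple[str, float]:
    """Present/marginal/absent call from discrimination scores.

    p < alpha1 → present; alpha1 <= p < alpha2 → marginal; else absent.
    """
    if not (0 < alpha1 < alpha2 < 1):
        raise ConfigError("need 0 < alpha1 < alpha2 < 1")
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise InputError("no discrimination scores")
    p = wilcoxon_signed_rank_right_p(scores - tau)
    if p < alpha1:
        return PRESENT, p
    if p < alpha2:
        return MARGINAL, p
    return ABSENT, p


def detection_calls_from_probes(probes: pd.DataFrame,
                                config: AnalysisConfig | None = None
                                ) -> pd.DataFrame:
    """Detection calls for a long-format probe-level table.

    ``probes`` needs columns gene, sample, pm, mm (one row per probe
    pair).  Returns a table with columns gene, sample, call, p.
    """
    config = config or AnalysisConfig()
    required = {"gene", "sample", "pm", "mm"}
    if not required.issubset(probes.columns):
        raise InputError(f"probe table needs columns {sorted(required)}")
    out = []
    for (gene, sample), grp in probes.groupby(["gene", "sample"], sort=True):
        r = discrimination_scores(grp["pm"].to_numpy(), grp["mm"].to_numpy())
        call, p = detection_call(r, config.tau, config.alpha1, config.alpha2)
        out.append((normalize_symbol(gene), sample, call, p))
    return pd.DataFrame(out, columns=["gene", "sample", "call", "p"])


def signed_fold_change(mean_exp: float, mean_ctrl: float) -> float:
    """Signed fold change of an experimental mean over a control mean.

    Returns ``mean_exp/mean_ctrl`` when the gene did not decrease, else
    ``-(mean_ctrl/mean_exp)``; |result| >= 1 always.  Non-positive means
    are errors: the codomain must stay finite.
    """
    if mean_exp <= 0 or mean_ctrl <= 0:
        raise InputError("group means must be strictly positive")
    ratio = mean_exp / mean_ctrl
    return ratio if ratio >= 1 else -1.0 / ratio


def _present_in_all(calls: pd.DataFrame, gene: str, samples: list[str]) -> bool:
    sub = calls[(calls["gene"] == gene) & (calls["sample"].isin(samples))]
    if len(sub) < len(samples):
        return False
    return bool((sub["call"] == PRESENT).all())


def select_changed_genes(expr: ExpressionMatrix,
                         calls: pd.DataFrame | None = None,
                         config: AnalysisConfig | None = None
                         ) -> dict[str, pd.DataFrame]:
    """Per-side tables of genes changed vs naive under the selection rules.

    A gene is retained for a side iff |signed fold change of that side's
    group mean vs the naive mean| >= fold_change_cutoff AND the presence
    gate holds.  The default gate requires a present call in all
    ipsilateral samples or in all contralateral samples, and the same gate
    applies to both sides.  ``calls=None`` treats every gene as present.

    Returns ``{"ipsilateral": df, "contralateral": df}`` with columns
    gene, signed_fc, present_ok (only retained genes).
    """
    config = config or AnalysisConfig()
    if not expr.samples_in(NAIVE):
        raise ConfigError("expression matrix has no naive samples")
    naive_mean = expr.group_mean(NAIVE)

    if calls is None or config.presence_rule == "none":
        present_ok = pd.Series(True, index=expr.values.index)
    else:
        ipsi_samples = expr.samples_in(IPSI)
        contra_samples = expr.samples_in(CONTRA)
        # pivot to wide boolean "present" per gene x sample
        wide = (calls.assign(ok=calls["call"] == PRESENT)
                .pivot_table(index="gene", columns="sample", values="ok",
                             aggfunc="all", fill_value=False))
        wide = wide.reindex(expr.values.index, fill_value=False)
        all_ipsi = wide.reindex(columns=ipsi_samples, fill_value=False).all(axis=1) \
            if ipsi_samples else pd.Series(False, index=wide.index)
        all_contra = wide.reindex(columns=contra_samples, fill_value=False).all(axis=1) \
            if contra_samples else pd.Series(False, index=wide.index)
        present_ok = all_ipsi | all_contra

    result: dict[str, pd.DataFrame] = {}
    for side in (IPSI, CONTRA):
        if not expr.samples_in(side):
            result[side] = pd.DataFrame(columns=["gene", "signed_fc", "present_ok"])
            continue
        side_mean = expr.group_mean(side)
        # relative tolerance keeps genes sitting exactly at the cutoff from
        # flipping on float rounding of the replicate means
        cutoff = config.fold_change_cutoff * (1 - 1e-12)
        rows = []
        for gene in expr.values.index:
            fc = signed_fold_change(float(side_mean[gene]),
                                    float(naive_mean[gene]))
            if abs(fc) >= cutoff and bool(present_ok[gene]):
                rows.append((gene, fc, True))
        result[side] = pd.DataFrame(rows,
                                    columns=["gene", "signed_fc", "present_ok"])
    return result
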