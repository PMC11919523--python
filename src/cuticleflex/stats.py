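"""Nonparametric statistics for layer-wise and mode-wise comparisons.

Sample sizes in this kind of in-situ scanning experiment are small (4-9
specimens), so every test uses the exact small-sample null distribution
where it is available: the Wilcoxon signed-rank test for paired exocuticle
vs endocuticle values, the Mann-Whitney U test with Holm step-down
adjustment for compression-vs-tension families, and an aligned
rank transform (ART) split-plot ANOVA for the mode (between-specimen) by
layer (within-specimen) design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSamples",
    "wilcoxon_signed_rank",
    "mann_whitney_holm",
    "art_mixed_anova",
    "holm_adjust",
    "significance_stars",
]


@dataclass(frozen=True)
class PairedSamples:
    """Per-specimen paired values, e.g. exocuticle vs endocuticle pre-strain."""

    first: tuple
    second: tuple

    def __post_init__(self) -> None:
        if len(self.first) != len(self.second):
            raise ValueError("paired samples must have equal length")
        if len(self.first) < 2:
            raise ValueError("need at least 2 pairs")

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.first, dtype=float) - np.asarray(
            self.second, dtype=float
        )


def wilcoxon_signed_rank(paired: PairedSamples) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (with a warning).  For n <= 25 without
    ties the p value is exact (enumeration of the 2^n sign assignments of
    the rank sum); otherwise the normal approximation with tie correction
    is used.  Returns ``(W, p)`` with W the larger of the signed-rank sums.
    """
    d = paired.differences
    nz = d[d != 0]
    if len(nz) == 0:
        raise ValueError("all paired differences are zero")
    if len(nz) < len(d):
        warnings.warn(
            f"dropping {len(d) - len(nz)} zero difference(s)", stacklevel=2
        )
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method)
    w_plus = float(res.statistic)  # scipy returns min(W+, W-)
    n = len(nz)
    w = max(w_plus, n * (n + 1) / 2 - w_plus)
    return w, float(res.pvalue)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of a family of p values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="holm")[1]


def mann_whitney_holm(comparisons) -> list[dict]:
    """Mann-Whitney U tests over a family, Holm-adjusted.

    ``comparisons`` is a sequence of (name, group1, group2) or
    (group1, group2) tuples.  The U null distribution is exact for
    n1 + n2 <= 12 without ties, asymptotic (tie-corrected, continuity
    corrected) otherwise.  Returns one dict per comparison with U, raw and
    Holm-adjusted two-sided p values.
    """
    named = []
    for i, comp in enumerate(comparisons):
        if len(comp) == 3:
            named.append(comp)
        else:
            named.append((f"comparison_{i}", comp[0], comp[1]))
    results = []
    for name, g1, g2 in named:
        a, b = np.asarray(g1, float), np.asarray(g2, float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"{name}: each group needs at least 2 values")
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) + len(b) <= 12 and not ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        results.append(
            dict(name=name, U=float(res.statistic), p_raw=float(res.pvalue))
        )
    adj = holm_adjust([r["p_raw"] for r in results])
    for r, p in zip(results, adj):
        r["p_holm"] = float(p)
    return results


def _splitplot_anova(df: pd.DataFrame, response: str) -> dict[str, dict]:
    """Classical split-plot F tests: mode between subjects, layer within.

    Whole-plot error is subjects-within-mode; subplot error is the
    layer-by-subject residual.  Balanced within subjects (every subject
    contributes every layer); group sizes may differ between modes.
    """
    y = df[response].to_numpy(dtype=float)
    grand = y.mean()
    n_layers = df["layer"].nunique()
    n_modes = df["mode"].nunique()
    subj_means = df.groupby("subject")[response].mean()
    subj_mode = df.groupby("subject")["mode"].first()
    n_subj = len(subj_means)

    ss_total = float(np.sum((y - grand) ** 2))
    ss_between = n_layers * float(np.sum((subj_means - grand) ** 2))
    mode_means = df.groupby("mode")[response].mean()
    counts = subj_mode.value_counts()
    ss_mode = n_layers * float(
        sum(counts[m] * (mode_means[m] - grand) ** 2 for m in mode_means.index)
    )
    ss_subj = ss_between - ss_mode
    layer_means = df.groupby("layer")[response].mean()
    ss_layer = n_subj * float(np.sum((layer_means - grand) ** 2))
    cell_means = df.groupby(["mode", "layer"])[response].mean()
    ss_inter = float(
        sum(
            counts[m]
            * (cell_means[(m, l)] - mode_means[m] - layer_means[l] + grand) ** 2
            for m, l in cell_means.index
        )
    )
    ss_within = ss_total - ss_between
    ss_err = ss_within - ss_layer - ss_inter

    df_mode = n_modes - 1
    df_subj = n_subj - n_modes
    df_layer = n_layers - 1
    df_inter = df_mode * df_layer
    df_err = df_subj * df_layer

    def f_test(ss, dfn, ss_e, dfe):
        if dfn <= 0 or dfe <= 0 or ss_e <= 1e-12:
            return dict(F=float("nan"), df1=dfn, df2=dfe, p=float("nan"),
                        degenerate=True)
        f = (ss / dfn) / (ss_e / dfe)
        return dict(F=float(f), df1=dfn, df2=dfe,
                    p=float(sps.f.sf(f, dfn, dfe)), degenerate=False)

    return dict(
        mode=f_test(ss_mode, df_mode, ss_subj, df_subj),
        layer=f_test(ss_layer, df_layer, ss_err, df_err),
        interaction=f_test(ss_inter, df_inter, ss_err, df_err),
    )


def art_mixed_anova(data, posthoc: bool = True) -> dict:
    """Aligned-rank-transform split-plot ANOVA for mode x layer designs.

    ``data`` needs columns ``subject``, ``mode`` (between-subject),
    ``layer`` (within-subject) and ``value``; every subject must have one
    value per layer.  For each effect the response is aligned (all other
    estimated effects subtracted, the target effect retained), ranked
    across the whole data set and submitted to the split-plot ANOVA with
    the appropriate error stratum.  Post hoc: paired Wilcoxon between
    layers within each mode, Holm-adjusted.  Degenerate (constant) data
    yields NaN F/p flagged with ``degenerate=True``.
    """
    df = pd.DataFrame(data).copy()
    required = {"subject", "mode", "layer", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    layout = df.groupby(["subject", "layer"]).size()
    if (layout != 1).any() or df.groupby("subject")["layer"].nunique().nunique() != 1:
        raise ValueError("incomplete design: every subject needs one value per layer")

    grand = df["value"].mean()
    mode_eff = df.groupby("mode")["value"].mean() - grand
    layer_eff = df.groupby("layer")["value"].mean() - grand
    cell_mean = df.groupby(["mode", "layer"])["value"].transform("mean")
    resid = df["value"] - cell_mean
    inter_eff = (
        cell_mean
        - df["mode"].map(mode_eff)
        - df["layer"].map(layer_eff)
        - grand
    )

    aligned = {
        "mode": resid + df["mode"].map(mode_eff).to_numpy(),
        "layer": resid + df["layer"].map(layer_eff).to_numpy(),
        "interaction": resid + inter_eff.to_numpy(),
    }
    out = {}
    for effect, vals in aligned.items():
        work = df.assign(_art=sps.rankdata(vals))
        out[effect] = _splitplot_anova(work, "_art")[effect]

    if posthoc:
        ph = []
        layers = sorted(df["layer"].unique())
        for mode, g in df.groupby("mode"):
            if len(layers) != 2:
                break
            wide = g.pivot(index="subject", columns="layer", values="value")
            try:
                w, p = wilcoxon_signed_rank(
                    PairedSamples(
                        tuple(wide[layers[0]]), tuple(wide[layers[1]])
                    )
                )
                ph.append(dict(mode=mode, W=w, p_raw=p))
            except ValueError:
                ph.append(dict(mode=mode, W=float("nan"), p_raw=float("nan")))
        ps = [r["p_raw"] for r in ph]
        if ps and np.all(np.isfinite(ps)):
            for r, p in zip(ph, holm_adjust(ps)):
                r["p_holm"] = float(p)
        out["posthoc_layer_within_mode"] = ph
    return out


def significance_stars(p: float) -> str:
    """Conventional significance markers at 0.05 / 0.01 / 0.001."""
    if not np.isfinite(p):
        return "n/a"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
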