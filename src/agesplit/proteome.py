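"""TMT proteome statistics: batch normalization, presence filter, ANOVA+Tukey.

The protein layer arrives as reporter-ion intensities quantified in two
isobaric-labelling batches (a 10-plex and a 16-plex kit). Processing follows
the minimal published recipe: rescale one batch so the two batch means agree,
keep proteins present in more than a given fraction of samples (strictly
greater than, 70% by default), then test each protein across the three
groups with one-way ANOVA on log2 intensities, BH-adjusted q-values, and
Tukey-Kramer post-hoc pairwise comparisons. A pairwise change requires both
q < 0.05 and Tukey p < 0.05.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import ProteinMatrix


def batch_normalize(pm: ProteinMatrix, reference_batch: str | None = None) -> ProteinMatrix:
    """Equalize the mean intensity of the two labelling batches.

    The non-reference batch is rescaled by (mean of reference batch) /
    (mean of that batch), means taken over present values only. By default
    the lexicographically larger batch label is the reference, which for the
    conventional labels scales "10-plex" onto "16-plex". Idempotent.
    """
    batches = sorted(pd.unique(pm.batch))
    if len(batches) != 2:
        raise ValueError(f"expected exactly two batches, got {batches}")
    if reference_batch is None:
        reference_batch = batches[1]
    other = batches[0] if reference_batch == batches[1] else batches[1]

    x = pm.intensities
    ref_cols = pm.batch.index[pm.batch == reference_batch]
    oth_cols = pm.batch.index[pm.batch == other]
    ref_mean = x[ref_cols].to_numpy().ravel()
    oth_mean = x[oth_cols].to_numpy().ravel()
    ref_mean = np.nanmean(ref_mean)
    oth_mean = np.nanmean(oth_mean)
    if not np.isfinite(ref_mean) or not np.isfinite(oth_mean) or oth_mean == 0:
        raise ValueError("a batch has no present values")
    scaled = x.copy()
    scaled[oth_cols] = x[oth_cols] * (ref_mean / oth_mean)
    return ProteinMatrix(intensities=scaled, batch=pm.batch, groups=pm.groups)


def filter_proteins(pm: ProteinMatrix, presence_fraction: float = 0.70) -> ProteinMatrix:
    """Keep proteins present in strictly more than ``presence_fraction`` of samples."""
    if not 0 < presence_fraction <= 1:
        raise ValueError("presence_fraction must lie in (0, 1]")
    frac = pm.intensities.notna().mean(axis=1)
    keep = frac > presence_fraction
    return ProteinMatrix(
        intensities=pm.intensities.loc[keep], batch=pm.batch, groups=pm.groups
    )


def _anova_masked(x: np.ndarray, group_masks: list[np.ndarray]):
    """Vectorised one-way ANOVA over rows with missing values.

    Returns (F, p, msw, df_within, group_means, group_ns, testable).
    A protein is testable when every group has >= 2 present values.
    """
    k = len(group_masks)
    n_rows = x.shape[0]
    means = np.full((n_rows, k), np.nan)
    ns = np.zeros((n_rows, k), dtype=int)
    ssw = np.zeros(n_rows)
    for j, m in enumerate(group_masks):
        sub = x[:, m]
        ns[:, j] = np.sum(~np.isnan(sub), axis=1)
        with np.errstate(invalid="ignore"):
            means[:, j] = np.nanmean(sub, axis=1)
            dev = sub - means[:, j][:, None]
            ssw += np.nansum(dev * dev, axis=1)
    testable = np.all(ns >= 2, axis=1)
    n_tot = ns.sum(axis=1)
    with np.errstate(invalid="ignore"):
        grand = np.nansum(means * ns, axis=1) / n_tot
        ssb = np.nansum(ns * (means - grand[:, None]) ** 2, axis=1)
    df_b = k - 1
    df_w = n_tot - k
    with np.errstate(invalid="ignore", divide="ignore"):
        msb = ssb / df_b
        msw = np.where(df_w > 0, ssw / np.maximum(df_w, 1), np.nan)
        F = msb / msw
    # all-values-identical convention: F = 0, p = 1
    degen = testable & (ssw <= 1e-300) & (ssb <= 1e-300)
    with np.errstate(invalid="ignore"):
        p = stats.f.sf(F, df_b, df_w)
    F = np.where(degen, 0.0, F)
    p = np.where(degen, 1.0, p)
    return F, p, msw, df_w, means, ns, testable


def anova_tukey(
    pm: ProteinMatrix,
    log_transform: bool = True,
    q_threshold: float = 0.05,
    tukey_threshold: float = 0.05,
    tukey_scope: str = "all",
) -> pd.DataFrame:
    """Per-protein one-way ANOVA with q-values and Tukey-Kramer post hocs.

    Missing values are excluded per protein (no imputation); Tukey-Kramer
    handles the resulting unbalanced group sizes through the pairwise
    standard error ``sqrt(MSW/2 * (1/n_i + 1/n_j))``. Output columns per
    group pair: ``tukey_p_{A}_vs_{B}``, ``dir_{A}_vs_{B}`` (sign of the
    log2 mean difference A - B) and ``sig_{A}_vs_{B}``
    (q < ``q_threshold`` and Tukey p < ``tukey_threshold``).

    ``tukey_scope="candidates"`` evaluates the studentized-range p only for
    proteins with q < ``q_threshold`` (the only rows whose significance
    flags can depend on it); other rows get NaN Tukey p. Flags are
    identical to ``tukey_scope="all"``, which fills in every p.
    """
    if tukey_scope not in ("all", "candidates"):
        raise ValueError("tukey_scope must be 'all' or 'candidates'")
    x = pm.intensities.to_numpy(dtype=float)
    if log_transform:
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.log2(x)
    group_labels = list(pd.unique(pm.groups.loc[pm.intensities.columns]))
    if len(group_labels) < 2:
        raise ValueError("need >=2 groups")
    sample_groups = pm.groups.loc[pm.intensities.columns].to_numpy()
    masks = [sample_groups == g for g in group_labels]

    F, p, msw, df_w, means, ns, testable = _anova_masked(x, masks)
    q = np.full_like(p, np.nan)
    if testable.any():
        q[testable] = multipletests(p[testable], method="fdr_bh")[1]

    out = pd.DataFrame(
        {"anova_F": F, "anova_p": np.where(testable, p, np.nan), "q_value": q,
         "testable": testable},
        index=pm.intensities.index,
    )
    k = len(group_labels)
    for i, j in combinations(range(k), 2):
        a, b = group_labels[i], group_labels[j]
        diff = means[:, i] - means[:, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(msw / 2.0 * (1.0 / ns[:, i] + 1.0 / ns[:, j]))
            qstat = np.abs(diff) / se
        tp = np.full_like(qstat, np.nan)
        ok = testable & np.isfinite(qstat) & (df_w > 0)
        if tukey_scope == "candidates":
            ok &= q < q_threshold
        if ok.any():
            tp[ok] = stats.studentized_range.sf(qstat[ok], k, df_w[ok])
        # zero-MSW degenerate rows: a nonzero mean difference with no
        # within-group scatter is maximally significant; no difference at
        # all gets p = 1
        zero_msw = testable & ~np.isfinite(qstat) & (df_w > 0)
        tp = np.where(zero_msw & (np.abs(diff) > 0), 0.0, tp)
        tp = np.where(zero_msw & (np.abs(diff) == 0), 1.0, tp)
        name = f"{a}_vs_{b}"
        out[f"tukey_p_{name}"] = tp
        out[f"dir_{name}"] = np.sign(diff)
        out[f"sig_{name}"] = (out["q_value"] < q_threshold) & (tp < tukey_threshold)
        out[f"mean_log2_{a}"] = means[:, i]
        out[f"mean_log2_{b}"] = means[:, j]
    return out


def pairwise_status(result: pd.DataFrame, pair: tuple[str, str]) -> pd.Series:
    """Map a Tukey pair to up/down/ns for ``pair = (numerator, denominator)``.

    The stored pair columns are oriented by group order of first appearance;
    this helper flips the sign when the requested orientation is reversed.
    """
    num, den = pair
    if f"sig_{num}_vs_{den}" in result.columns:
        name, flip = f"{num}_vs_{den}", 1.0
    elif f"sig_{den}_vs_{num}" in result.columns:
        name, flip = f"{den}_vs_{num}", -1.0
    else:
        raise KeyError(f"no Tukey columns for pair {pair}")
    sig = result[f"sig_{name}"].fillna(False)
    direction = result[f"dir_{name}"] * flip
    status = np.where(sig & (direction > 0), "up",
                      np.where(sig & (direction < 0), "down", "ns"))
    return pd.Series(status, index=result.index, name=f"protein_status_{num}_vs_{den}")
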