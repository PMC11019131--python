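"""Cross-layer integration: concordance, primary-aging selection, trajectories.

The heart of the analysis is the separation of two effect axes in the
three-group design (young healthy YH, young patients YP, older patients OP):

* changes shared by both patient groups against YH reflect chronic
  inflammation / inactivity (secondary aging);
* changes present in OP against *both* YH and YP — the same direction in the
  OP-vs-YP and OP-vs-YH comparisons — are attributed to primary aging.

Selection runs at the protein level where a protein was quantified, falling
back to the mRNA level for undetected proteins; mRNAs whose protein product
was measured but did not change are excluded, since the protein is the
functional endpoint.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

CONCORDANCE_CLASSES = (
    "protein UP-mRNA UP",
    "protein UP-mRNA NS",
    "protein UP-mRNA DOWN",
    "protein DOWN-mRNA DOWN",
    "protein DOWN-mRNA NS",
    "protein DOWN-mRNA UP",
)


def classify_concordance(
    mrna_status: pd.Series, protein_status: pd.Series
) -> pd.DataFrame:
    """Joint protein/mRNA status classes for one group comparison.

    ``mrna_status`` holds up/down/ns per gene; ``protein_status`` holds
    up/down/ns per quantified protein (genes absent from it are
    ``undetected``). Proteins with a significant change are partitioned into
    the six classes (e.g. "protein DOWN-mRNA NS"); everything else maps to
    "none". The ``attrs['summary']`` carries class counts and the fraction
    of changed proteins whose mRNA moved the same way (the transcriptionally
    driven fraction).
    """
    genes = protein_status.index
    shared = genes.intersection(mrna_status.index)
    skipped = genes.difference(mrna_status.index)

    prot = protein_status.loc[shared]
    mrna = mrna_status.loc[shared]
    label = np.full(len(shared), "none", dtype=object)
    changed = prot.isin(["up", "down"]).to_numpy()
    pu = (prot == "up").to_numpy()
    mapping = {"up": "UP", "down": "DOWN", "ns": "NS"}
    for i, g in enumerate(shared):
        if not changed[i]:
            continue
        label[i] = (
            f"protein {'UP' if pu[i] else 'DOWN'}-mRNA {mapping[mrna.iloc[i]]}"
        )
    out = pd.DataFrame(
        {"protein_status": prot, "mrna_status": mrna, "concordance_class": label},
        index=shared,
    )
    counts = out.loc[changed, "concordance_class"].value_counts().to_dict()
    n_changed = int(changed.sum())
    n_concordant = int(
        counts.get("protein UP-mRNA UP", 0) + counts.get("protein DOWN-mRNA DOWN", 0)
    )
    out.attrs["summary"] = {
        "class_counts": counts,
        "n_protein_changed": n_changed,
        "concordant_fraction": (n_concordant / n_changed) if n_changed else np.nan,
        "n_skipped_no_mrna": int(len(skipped)),
    }
    return out


def select_primary_aging(
    de_op_yp: pd.DataFrame,
    de_op_yh: pd.DataFrame,
    prot_status_op_yp: pd.Series,
    prot_status_op_yh: pd.Series,
    detected_proteins: pd.Index | None = None,
    lenient: bool = False,
) -> pd.DataFrame:
    """Direction-consistent primary-aging gene selection.

    Protein evidence: the protein changed significantly in the same
    direction in OP-vs-YP and OP-vs-YH. mRNA evidence: the gene is a DEG in
    the same direction in both comparisons, and its protein is either not
    quantified or itself changed — quantified-but-unchanged proteins veto
    the mRNA call. ``lenient`` relaxes the protein rule to significance in
    one comparison plus a same-sign trend in the other (off by default).

    Returns a table indexed by gene with ``direction`` (up/down),
    ``evidence`` (protein/mRNA) and supporting statistics.
    """
    if detected_proteins is None:
        detected_proteins = prot_status_op_yh.index.union(prot_status_op_yp.index)

    rows = []
    # protein-evidence members
    shared_prot = prot_status_op_yp.index.intersection(prot_status_op_yh.index)
    s1 = prot_status_op_yp.loc[shared_prot]
    s2 = prot_status_op_yh.loc[shared_prot]
    if lenient:
        prot_dir = pd.Series("ns", index=shared_prot, dtype=object)
        for d in ("up", "down"):
            one_sig = ((s1 == d) & (s2 != {"up": "down", "down": "up"}[d])) | (
                (s2 == d) & (s1 != {"up": "down", "down": "up"}[d])
            )
            prot_dir[one_sig & ((s1 == d) | (s2 == d))] = d
        prot_members = prot_dir[prot_dir.isin(["up", "down"])]
    else:
        same = (s1 == s2) & s1.isin(["up", "down"])
        prot_members = s1[same]
    for g, d in prot_members.items():
        rows.append({"gene_id": g, "direction": d, "evidence": "protein"})

    # mRNA-evidence members
    shared = de_op_yp.index.intersection(de_op_yh.index)
    st1 = de_op_yp.loc[shared, "deg_status"]
    st2 = de_op_yh.loc[shared, "deg_status"]
    same_mrna = (st1 == st2) & st1.isin(["up", "down"])
    prot_changed = set(prot_members.index)
    for g in shared[same_mrna]:
        if g in prot_changed:
            continue  # already in at the protein level
        if g in detected_proteins:
            # quantified protein that did not change in both comparisons
            # vetoes the mRNA call
            ch1 = prot_status_op_yp.get(g, "ns")
            ch2 = prot_status_op_yh.get(g, "ns")
            if ch1 == "ns" and ch2 == "ns":
                continue
        rows.append({"gene_id": g, "direction": st1[g], "evidence": "mRNA"})

    out = pd.DataFrame(rows, columns=["gene_id", "direction", "evidence"])
    out = out.drop_duplicates("gene_id").set_index("gene_id").sort_index()
    for name, de in (("OP_vs_YP", de_op_yp), ("OP_vs_YH", de_op_yh)):
        out[f"log2_fc_{name}"] = de["log2_fc"].reindex(out.index)
        out[f"padj_{name}"] = de["padj"].reindex(out.index)
    return out


def trajectory_zscores(
    matrix: pd.DataFrame,
    groups: pd.Series,
    feature_subset: pd.Index | None = None,
    group_order: tuple[str, ...] = ("YH", "YP", "OP"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature z-scores across all samples plus per-group mean z.

    Standardization uses the population standard deviation (ddof=0) over all
    samples, so each retained feature has mean 0 and sd 1 exactly.
    Zero-variance features are skipped. Returns (z, group_means) where
    ``group_means`` columns follow ``group_order`` — the YH→YP→OP
    trajectory axis.
    """
    x = matrix
    if feature_subset is not None:
        x = x.loc[x.index.intersection(feature_subset)]
    vals = x.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, ddof=0, keepdims=True)
    keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    z = pd.DataFrame(
        (vals[keep] - mean[keep]) / sd[keep], index=x.index[keep], columns=x.columns
    )
    gm = {}
    for g in group_order:
        cols = [s for s in z.columns if groups.get(s) == g]
        if cols:
            gm[g] = z[cols].mean(axis=1)
    return z, pd.DataFrame(gm)


def overlap_test(
    set_a: set, set_b: set, universe_size: int
) -> tuple[float, float]:
    """Sample odds ratio and one-sided hypergeometric over-representation p.

    The 2x2 table is (both, a only, b only, neither) over a universe of
    ``universe_size`` genes; p is P(overlap >= observed).
    """
    a, b = set(set_a), set(set_b)
    na, nb = len(a), len(b)
    if max(na, nb) > universe_size:
        raise ValueError("set larger than universe")
    k = len(a & b)
    neither = universe_size - na - nb + k
    if neither < 0:
        raise ValueError("sets overlap less than universe allows")
    p = float(stats.hypergeom.sf(k - 1, universe_size, na, nb))
    denom = (na - k) * (nb - k)
    odds = (k * neither / denom) if denom > 0 else np.inf
    return odds, p


def pca_qc(
    matrix: pd.DataFrame, log_transform: bool = True, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples on log expression, for profile-level QC.

    Returns per-sample PC coordinates and the explained-variance fractions
    (non-increasing, summing to <= 1).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = matrix.to_numpy(dtype=float).T  # samples x features
    if log_transform:
        x = np.log2(x + 1.0)
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(x - x.mean(axis=0, keepdims=True))
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
    )
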