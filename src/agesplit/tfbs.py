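"""Promoter transcription-factor-binding-site enrichment.

Scans promoters on both strands with TRANSFAC-style position weight matrices
(PWMs) using log-odds scores against the background base composition. Per
PWM, the score threshold is calibrated on a pool of background promoters so
that the background site frequency does not exceed a cap (1 site per 2000
scanned bp by default). Enrichment of foreground promoters over a sampled
background (non-differentially-expressed promoters) is summarized by the
adjusted fold enrichment FE_adj: the 99%-confidence lower bound of the odds
ratio (Woolf standard error on the log odds ratio, Haldane-Anscombe +0.5 on
zero cells), computed both on site frequencies and on promoter hit counts.
Significance combines FE_adj > 1 in both variants with an FDR < 0.05 on the
one-sided binomial site-count test; an exact one-sided Fisher test on the
promoter table is reported alongside. PWMs of the same factor are collapsed
to the most enriched one, and factors not expressed in the older-patient
group (TPM <= 1) are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import PromoterSet

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DEFAULT_MAX_FREQ = 1.0 / 2000.0  # sites per scanned bp
Z_99 = float(stats.norm.ppf(0.995))


@dataclass
class PWM:
    """Position weight matrix: per-position base counts plus tf name."""

    matrix_id: str
    tf_name: str
    counts: np.ndarray  # width x 4, order ACGT
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("PWM counts must be width x 4")
        if self.counts.shape[0] < 4:
            raise ValueError("PWM width must be >= 4")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError("PWM has an all-zero column")
        if np.any(self.counts < 0):
            raise ValueError("PWM counts must be non-negative")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def probs(self) -> np.ndarray:
        """Pseudocount-normalized per-position base frequencies (rows sum to 1)."""
        c = self.counts + self.pseudocount
        return c / c.sum(axis=1, keepdims=True)

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        """log2(p / background) per position and base."""
        bg = np.asarray(background, dtype=float)
        return np.log2(self.probs / bg[None, :])

    def max_score(self, background: np.ndarray) -> float:
        return float(self.log_odds(background).max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix_id, self.tf_name, self.counts[::-1, ::-1],
                   self.pseudocount)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


@dataclass
class PWMSet:
    pwms: list[PWM] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.matrix_id for p in self.pwms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate matrix ids")

    def __iter__(self):
        return iter(self.pwms)

    def __len__(self) -> int:
        return len(self.pwms)

    def __getitem__(self, matrix_id: str) -> PWM:
        for p in self.pwms:
            if p.matrix_id == matrix_id:
                return p
        raise KeyError(matrix_id)


def read_transfac(path: str | Path) -> PWMSet:
    """Parse a TRANSFAC-dialect PWM file (AC/ID/DE/P0 blocks)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "TRANSFAC")
    pwms = []
    for m in parsed:
        counts = np.column_stack([np.asarray(m.counts[b], dtype=float) for b in BASES])
        matrix_id = m.get("ID") or m.get("AC") or f"M{len(pwms):05d}"
        tf_name = (m.get("DE") or matrix_id).split()[0]
        pwms.append(PWM(matrix_id=matrix_id, tf_name=tf_name, counts=counts))
    return PWMSet(pwms)


def write_transfac(pwm_set: PWMSet, path: str | Path) -> None:
    lines = []
    for p in pwm_set:
        lines += [f"AC  {p.matrix_id}", "XX", f"ID  {p.matrix_id}", "XX",
                  f"DE  {p.tf_name}", "XX",
                  "P0      A      C      G      T"]
        for i in range(p.width):
            vals = "      ".join(f"{v:g}" for v in p.counts[i])
            lines.append(f"{i + 1:02d}      {vals}")
        lines += ["XX", "//"]
    Path(path).write_text("\n".join(lines) + "\n")


def consensus_pwm(matrix_id: str, tf_name: str, consensus: str,
                  strength: float = 100.0) -> PWM:
    """A near-deterministic PWM for a consensus sequence (test helper)."""
    counts = np.ones((len(consensus), 4))
    for i, b in enumerate(consensus.upper()):
        counts[i, _BASE_INDEX[b]] = strength
    return PWM(matrix_id, tf_name, counts)


def random_pwm(matrix_id: str, tf_name: str, width: int, rng,
               concentration: float = 0.5, scale: float = 100.0) -> PWM:
    """Random Dirichlet-column PWM, used to build decoy motif libraries."""
    probs = rng.dirichlet(np.full(4, concentration), size=width)
    return PWM(matrix_id, tf_name, probs * scale + 1e-6)


# ---------------------------------------------------------------------------
# scanning


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3; any other letter (incl. N) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _score_positions(enc: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score at every start position of one encoded sequence."""
    w = lom.shape[0]
    n = enc.size - w + 1
    if n <= 0:
        return np.empty(0)
    # pad the 4-letter alphabet with a -inf column for N
    lom_pad = np.hstack([lom, np.full((w, 1), -np.inf)])
    scores = np.zeros(n)
    for j in range(w):
        scores += lom_pad[j, enc[j:j + n]]
    return scores


def _concat_encode(promoters: PromoterSet) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    """All promoters in one encoded array, separated by a run of Ns.

    Returns the array plus per-promoter (gene, start, length) records; the
    16-N separator exceeds any allowed PWM start overlap, and windows
    touching a separator score -inf anyway.
    """
    cached = getattr(promoters, "_encode_cache", None)
    if cached is not None:
        return cached
    sep = np.full(64, 4, dtype=np.int8)
    parts, spans, pos = [], [], 0
    for gene, seq in promoters.sequences.items():
        enc = encode_sequence(seq)
        parts.append(enc)
        spans.append((gene, pos, enc.size))
        pos += enc.size
        parts.append(sep)
        pos += sep.size
    enc_all = np.concatenate(parts) if parts else np.empty(0, dtype=np.int8)
    result = (enc_all.astype(np.intp), spans)
    promoters._encode_cache = result  # noqa: SLF001 - memoised per pool
    return result


def _strand_scores(pwm: PWM, promoters: PromoterSet, background: np.ndarray):
    """Per-strand score arrays over the concatenated pool plus promoter spans."""
    enc, spans = _concat_encode(promoters)
    lom_f = pwm.log_odds(background)
    lom_r = pwm.reverse_complement().log_odds(background)
    return _score_positions(enc, lom_f), _score_positions(enc, lom_r), spans


def scan_promoters(
    pwm: PWM,
    promoters: PromoterSet,
    threshold: float,
    background: np.ndarray,
) -> pd.DataFrame:
    """Count sites with log-odds score >= threshold on both strands.

    Overlapping sites are all counted; positions covering an N score -inf.
    Returns a per-promoter table with forward, reverse and total site counts
    and the number of scanned positions (both strands).
    """
    sf, sr, spans = _strand_scores(pwm, promoters, background)
    return _counts_from_scores(sf, sr, spans, pwm.width, threshold)


def _counts_from_scores(sf, sr, spans, w: int, threshold: float) -> pd.DataFrame:
    with np.errstate(invalid="ignore"):
        hit_f = sf >= threshold
        hit_r = sr >= threshold
    cum_f = np.concatenate([[0], np.cumsum(hit_f)])
    cum_r = np.concatenate([[0], np.cumsum(hit_r)])
    rows = []
    for gene, start, length in spans:
        n_pos = max(length - w + 1, 0)
        nf = int(cum_f[start + n_pos] - cum_f[start]) if n_pos else 0
        nr = int(cum_r[start + n_pos] - cum_r[start]) if n_pos else 0
        rows.append({
            "gene_id": gene, "fwd_sites": nf, "rev_sites": nr,
            "sites": nf + nr, "scanned_positions": 2 * n_pos,
        })
    return pd.DataFrame(rows).set_index("gene_id")


def _all_scores(pwm: PWM, promoters: PromoterSet, background: np.ndarray) -> np.ndarray:
    """Every in-promoter position score, both strands (separators excluded)."""
    w = pwm.width
    sf, sr, spans = _strand_scores(pwm, promoters, background)
    keep = np.zeros(sf.size, dtype=bool)
    for _, start, length in spans:
        n_pos = max(length - w + 1, 0)
        keep[start:start + n_pos] = True
    return np.concatenate([sf[keep], sr[keep]])


def background_composition(promoters: PromoterSet) -> np.ndarray:
    """A/C/G/T frequencies of a promoter pool (N excluded)."""
    counts = np.zeros(4)
    for seq in promoters.sequences.values():
        enc = encode_sequence(seq)
        counts += np.bincount(enc[enc < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("no ACGT bases in promoter pool")
    return counts / total


class UnscannablePWM(ValueError):
    """Raised when no threshold can bring the background site frequency under the cap."""


def calibrate_threshold(
    pwm: PWM,
    background_pool: PromoterSet,
    background: np.ndarray | None = None,
    max_freq: float = DEFAULT_MAX_FREQ,
) -> float:
    """Smallest log-odds threshold with background site frequency <= max_freq.

    Site frequency is sites per scanned position, both strands. The
    threshold is chosen from the observed score set, so the calibration is
    deterministic given the pool.
    """
    if background is None:
        background = background_composition(background_pool)
    if background_pool.total_bp < 10 * 2000:
        raise ValueError("background pool too small to calibrate (< 20 kbp)")
    scores = _all_scores(pwm, background_pool, background)
    return _threshold_from_scores(pwm, scores, max_freq)


def _threshold_from_scores(pwm: PWM, scores: np.ndarray, max_freq: float) -> float:
    scores = scores[np.isfinite(scores)]
    max_sites = int(np.floor(max_freq * scores.size))
    if max_sites < 1:
        raise ValueError("background pool too small for the frequency cap")
    srt = np.sort(scores)[::-1]
    # count of sites at threshold t = #(scores >= t); candidate thresholds
    # are observed scores. The k-th largest score (k = max_sites) admits at
    # most max_sites sites unless tied with the next one.
    t = srt[max_sites - 1]
    n_at_t = int(np.sum(scores >= t))
    if n_at_t > max_sites:
        # ties push us over the cap: move to the next strictly larger score
        larger = srt[srt > t]
        if larger.size == 0:
            raise UnscannablePWM(
                f"{pwm.matrix_id}: cannot meet site-frequency cap {max_freq:g}"
            )
        t = larger[-1]
    return float(t)


# ---------------------------------------------------------------------------
# enrichment statistics


def sample_background(
    non_de_promoters: PromoterSet, n: int = 5000, seed: int = 0
) -> PromoterSet:
    """Uniform sample without replacement from the non-DE promoter pool."""
    ids = list(non_de_promoters.sequences)
    if not ids:
        raise ValueError("empty background pool")
    if len(ids) < n:
        warnings.warn(
            f"background pool has {len(ids)} < {n} promoters; using all",
            stacklevel=2,
        )
        chosen = ids
    else:
        rng = np.random.default_rng(seed)
        chosen = [ids[i] for i in rng.choice(len(ids), size=n, replace=False)]
    return PromoterSet(
        {g: non_de_promoters.sequences[g] for g in chosen}, role="background_pool"
    )


def adjusted_fold_enrichment(
    a: float, b: float, c: float, d: float, ci: float = 0.99
) -> tuple[float, float]:
    """(raw odds ratio, CI lower bound) for the 2x2 table (a, b, c, d).

    The lower bound is exp(ln OR - z * SE) with the Woolf standard error
    sqrt(1/a + 1/b + 1/c + 1/d); cells get the Haldane-Anscombe +0.5 when
    any cell is zero.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("negative cell count")
    raw = (
        (cells[0] * cells[3]) / (cells[1] * cells[2])
        if cells[1] * cells[2] > 0
        else np.inf
    )
    if np.any(cells == 0):
        cells = cells + 0.5
    z = float(stats.norm.ppf(0.5 + ci / 2.0))
    ln_or = np.log((cells[0] * cells[3]) / (cells[1] * cells[2]))
    se = np.sqrt((1.0 / cells).sum())
    return float(raw), float(np.exp(ln_or - z * se))


def compute_enrichment(
    matrix_id: str,
    tf_name: str,
    fg_sites: int,
    fg_bp: int,
    bg_sites: int,
    bg_bp: int,
    fg_promoters_with_site: int,
    fg_promoters: int,
    bg_promoters_with_site: int,
    bg_promoters: int,
    ci: float = 0.99,
) -> dict:
    """One PWM's enrichment record from calibrated site and promoter counts.

    FE_adj_freq is the CI lower bound of the odds ratio of the
    site-frequency table (fg_sites, fg_bp - fg_sites | bg_sites,
    bg_bp - bg_sites); FE_adj_prom the promoter-count analogue. binom_p is
    the one-sided P(X >= fg_sites) for X ~ Binomial(fg_bp, bg rate);
    fisher_p the one-sided hypergeometric p of the promoter table.
    """
    if bg_bp <= 0:
        raise ValueError("zero background bp")
    or_freq, fe_freq = adjusted_fold_enrichment(
        fg_sites, fg_bp - fg_sites, bg_sites, bg_bp - bg_sites, ci
    )
    or_prom, fe_prom = adjusted_fold_enrichment(
        fg_promoters_with_site,
        fg_promoters - fg_promoters_with_site,
        bg_promoters_with_site,
        bg_promoters - bg_promoters_with_site,
        ci,
    )
    bg_rate = bg_sites / bg_bp
    if bg_rate <= 0:
        binom_p = 0.0 if fg_sites > 0 else 1.0
    else:
        binom_p = float(stats.binom.sf(fg_sites - 1, fg_bp, min(bg_rate, 1.0)))
    fisher_p = float(
        stats.hypergeom.sf(
            fg_promoters_with_site - 1,
            fg_promoters + bg_promoters,
            fg_promoters_with_site + bg_promoters_with_site,
            fg_promoters,
        )
    )
    return {
        "matrix_id": matrix_id,
        "tf_name": tf_name,
        "fg_sites": fg_sites,
        "fg_bp": fg_bp,
        "bg_sites": bg_sites,
        "bg_bp": bg_bp,
        "fg_promoters_with_site": fg_promoters_with_site,
        "fg_promoters": fg_promoters,
        "bg_promoters_with_site": bg_promoters_with_site,
        "bg_promoters": bg_promoters,
        "or_freq": or_freq,
        "FE_adj_freq": fe_freq,
        "or_prom": or_prom,
        "FE_adj_prom": fe_prom,
        "binom_p": binom_p,
        "fisher_p": fisher_p,
    }


def enrichment_scan(
    pwm_set: PWMSet,
    foreground: PromoterSet,
    background_pool: PromoterSet,
    max_freq: float = DEFAULT_MAX_FREQ,
    ci: float = 0.99,
) -> pd.DataFrame:
    """Calibrate, scan and score every PWM; one record per scannable PWM.

    PWMs that cannot satisfy the background frequency cap are skipped (their
    ids are listed in ``attrs['unscannable']``). The log-odds background
    composition is estimated from the background pool.
    """
    if background_pool.total_bp < 10 * 2000:
        raise ValueError("background pool too small to calibrate (< 20 kbp)")
    background = background_composition(background_pool)
    records, unscannable = [], []
    for pwm in pwm_set:
        # score the background pool once: it serves both threshold
        # calibration and the background site counts
        w = pwm.width
        sf, sr, spans = _strand_scores(pwm, background_pool, background)
        keep = np.zeros(sf.size, dtype=bool)
        for _, start, length in spans:
            keep[start:start + max(length - w + 1, 0)] = True
        try:
            thr = _threshold_from_scores(
                pwm, np.concatenate([sf[keep], sr[keep]]), max_freq
            )
        except UnscannablePWM:
            unscannable.append(pwm.matrix_id)
            continue
        fg = scan_promoters(pwm, foreground, thr, background)
        bg = _counts_from_scores(sf, sr, spans, w, thr)
        rec = compute_enrichment(
            pwm.matrix_id,
            pwm.tf_name,
            int(fg["sites"].sum()),
            int(fg["scanned_positions"].sum()),
            int(bg["sites"].sum()),
            int(bg["scanned_positions"].sum()),
            int((fg["sites"] > 0).sum()),
            len(fg),
            int((bg["sites"] > 0).sum()),
            len(bg),
            ci,
        )
        rec["threshold"] = thr
        records.append(rec)
    out = pd.DataFrame(records)
    out.attrs["unscannable"] = unscannable
    return out


def collapse_and_filter(
    records: pd.DataFrame,
    tf_expression_tpm: pd.Series | None = None,
    fdr_threshold: float = 0.05,
    tpm_threshold: float = 1.0,
) -> pd.DataFrame:
    """BH FDR over PWMs, per-TF collapse, expressed-TF filter.

    The FDR is computed on the binomial site-count p across all retained
    PWMs before collapsing. Per factor the PWM with the largest FE_adj_freq
    is kept (ties broken by smaller fisher_p, then matrix_id). Factors
    absent from ``tf_expression_tpm`` or with TPM <= ``tpm_threshold`` in
    the older-patient group are dropped. ``significant`` requires
    FE_adj > 1 in both variants and FDR < ``fdr_threshold``.
    """
    if records.empty:
        out = records.copy()
        out["fdr"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out = records.copy()
    out["fdr"] = multipletests(out["binom_p"], method="fdr_bh")[1]
    out = out.sort_values(
        ["tf_name", "FE_adj_freq", "fisher_p", "matrix_id"],
        ascending=[True, False, True, True],
    )
    out = out.groupby("tf_name", as_index=False).first()
    if tf_expression_tpm is not None:
        known = out["tf_name"].isin(tf_expression_tpm.index)
        if (~known).any():
            warnings.warn(
                f"dropping TFs missing from expression table: "
                f"{sorted(out.loc[~known, 'tf_name'])}",
                stacklevel=2,
            )
        out = out[known]
        out = out[
            tf_expression_tpm.loc[out["tf_name"]].to_numpy() > tpm_threshold
        ]
    out["significant"] = (
        (out["FE_adj_freq"] > 1.0)
        & (out["FE_adj_prom"] > 1.0)
        & (out["fdr"] < fdr_threshold)
    )
    return out.sort_values("FE_adj_freq", ascending=False).reset_index(drop=True)
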