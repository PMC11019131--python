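"""Synthetic multi-omics data with planted ground truth.

Generates every input of the pipeline — an RNA-seq count matrix for a
three-group design (young healthy YH, young patients YP, older patients OP),
a matched TMT-style protein intensity matrix with a two-kit batch structure,
and promoter sequences with transcription-factor motifs planted in a chosen
gene set — so that each downstream stage has a recovery test against known
truth.

Two axes of planted effects mirror the study design:

* ``pathology`` effects shift *both* patient groups (YP and OP) relative to
  YH — the signature of chronic inflammation / inactivity shared by young
  and older patients.
* ``primary`` effects shift OP relative to *both* YH and YP — the signature
  of primary aging, present only in the older group.

Counts are negative binomial with ``var = mu + alpha * mu**2`` (``alpha`` is
the per-gene dispersion). The protein layer realises three regulation modes:
``transcriptional`` (protein tracks the mRNA effect), ``post_transcriptional_only``
(protein-only effect, mRNA stays flat) and ``buffered`` (mRNA changes, protein
does not).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EFFECT_CLASSES = (
    "null",
    "pathology_up",
    "pathology_down",
    "primary_up",
    "primary_down",
)
PROTEIN_MODES = ("transcriptional", "post_transcriptional_only", "buffered")
CONTRASTS = (("YP", "YH"), ("OP", "YH"), ("OP", "YP"))

# fixed offsets from the master seed, so each stage is independently
# reproducible from the manifest
_SEED_OFFSETS = {"counts": 11, "proteome": 23, "promoters": 37, "background": 53}


def _child_seed(seed: int, stage: str) -> int:
    return (int(seed) + _SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class StudyDesign:
    """Parameters of one synthetic three-group study.

    Group sizes default to the 15 / 8 / 37 arms of the osteoarthritis
    cohort design; class fractions default to 150 primary-aging genes and
    1000 pathology genes per 10,000 genes.
    """

    n_genes: int = 10_000
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"YH": 15, "YP": 8, "OP": 37}
    )
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "null": 0.885,
            "pathology_up": 0.05,
            "pathology_down": 0.05,
            "primary_up": 0.0075,
            "primary_down": 0.0075,
        }
    )
    lfc_magnitude: float = 1.0
    dispersion: float = 0.05
    baseline_range: tuple[float, float] = (20.0, 5000.0)
    length_range: tuple[float, float] = (500.0, 10_000.0)
    size_factor_range: tuple[float, float] = (1.0, 1.0)
    protein_fraction: float = 0.15
    protein_mode_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "transcriptional": 0.5,
            "post_transcriptional_only": 0.25,
            "buffered": 0.25,
        }
    )
    protein_noise_sd: float = 0.3
    batch_ratio: float = 2.0
    missing_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >=2 samples, got {n}")
        fr = dict(self.class_fractions)
        unknown = set(fr) - set(EFFECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown effect classes: {sorted(unknown)}")
        if any(v < 0 or v > 1 for v in fr.values()):
            raise ValueError("class fractions must lie in [0, 1]")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if np.any(np.asarray(self.dispersion) <= 0):
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.protein_fraction <= 1:
            raise ValueError("protein_fraction must lie in [0, 1]")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")
        mf = dict(self.protein_mode_fractions)
        if set(mf) - set(PROTEIN_MODES):
            raise ValueError("unknown protein modes")
        if abs(sum(mf.values()) - 1.0) > 1e-9:
            raise ValueError("protein mode fractions must sum to 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_sizes"] = dict(self.group_sizes)
        d["class_fractions"] = dict(self.class_fractions)
        d["protein_mode_fractions"] = dict(self.protein_mode_fractions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyDesign":
        d = dict(d)
        for key in ("baseline_range", "length_range", "size_factor_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CountMatrix:
    """Gene-level counts with lengths, group labels and library size factors."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    gene_lengths: pd.Series  # bp, indexed by gene
    groups: pd.Series  # sample -> group label

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(self.gene_lengths.index):
            raise ValueError("counts and gene_lengths indexes disagree")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


@dataclass
class ProteinMatrix:
    """Reporter-ion intensities (NaN = missing) with batch and group labels."""

    intensities: pd.DataFrame  # proteins x samples, positive or NaN
    batch: pd.Series  # sample -> batch label
    groups: pd.Series  # sample -> group label


@dataclass
class PromoterSet:
    """Named promoter sequences (uppercase ACGTN)."""

    sequences: dict[str, str]
    role: str = "foreground"

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __len__(self) -> int:
        return len(self.sequences)


def _allocate_classes(design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    """Deterministic largest-remainder allocation of genes to effect classes."""
    fracs = np.array([dict(design.class_fractions).get(c, 0.0) for c in EFFECT_CLASSES])
    raw = fracs * design.n_genes
    counts = np.floor(raw).astype(int)
    rem = design.n_genes - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    labels = np.repeat(np.array(EFFECT_CLASSES), counts)
    rng.shuffle(labels)
    return labels


def _group_log2_offsets(effect_class: str, lfc: float) -> dict[str, float]:
    """Per-group log2 shifts relative to the YH baseline."""
    if effect_class == "null":
        return {"YH": 0.0, "YP": 0.0, "OP": 0.0}
    sign = 1.0 if effect_class.endswith("_up") else -1.0
    if effect_class.startswith("pathology"):
        return {"YH": 0.0, "YP": sign * lfc, "OP": sign * lfc}
    return {"YH": 0.0, "YP": 0.0, "OP": sign * lfc}


def simulate_counts(design: StudyDesign) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw an NB count matrix with planted pathology and primary effects.

    Returns the count matrix and a truth table with one row per gene:
    effect class, true mRNA log2 fold change per contrast, true protein
    log2 fold change per contrast, protein detection flag and regulation
    mode. Genes in ``post_transcriptional_only`` mode carry their class
    effect at the protein level only — their mRNA stays at baseline.
    """
    design.validate()
    rng = np.random.default_rng(_child_seed(design.seed, "counts"))

    genes = [f"G{i:05d}" for i in range(design.n_genes)]
    group_names = list(design.group_sizes)
    samples, group_of = [], {}
    for g in group_names:
        for i in range(design.group_sizes[g]):
            sid = f"{g}_{i + 1:02d}"
            samples.append(sid)
            group_of[sid] = g

    classes = _allocate_classes(design, rng)
    baseline = np.exp(
        rng.uniform(np.log(design.baseline_range[0]), np.log(design.baseline_range[1]),
                    design.n_genes)
    )
    lengths = np.exp(
        rng.uniform(np.log(design.length_range[0]), np.log(design.length_range[1]),
                    design.n_genes)
    ).round().astype(int)
    lo, hi = design.size_factor_range
    size_factors = np.exp(rng.uniform(np.log(lo), np.log(hi), len(samples)))
    alpha = np.broadcast_to(np.asarray(design.dispersion, dtype=float),
                            (design.n_genes,)).copy()

    # protein layer bookkeeping decided here because regulation mode feeds
    # back into whether the mRNA effect is realised at all
    detected = rng.random(design.n_genes) < design.protein_fraction
    mode_labels = np.array(PROTEIN_MODES)
    mode_p = np.array([dict(design.protein_mode_fractions)[m] for m in PROTEIN_MODES])
    modes = np.where(detected, rng.choice(mode_labels, design.n_genes, p=mode_p), "")

    mrna_offsets = np.zeros((design.n_genes, len(group_names)))
    prot_offsets = np.zeros((design.n_genes, len(group_names)))
    for i in range(design.n_genes):
        off = _group_log2_offsets(classes[i], design.lfc_magnitude)
        vec = np.array([off[g] for g in group_names])
        if detected[i]:
            if modes[i] == "transcriptional":
                mrna_offsets[i], prot_offsets[i] = vec, vec
            elif modes[i] == "post_transcriptional_only":
                prot_offsets[i] = vec
            else:  # buffered: mRNA moves, protein does not
                mrna_offsets[i] = vec
        else:
            mrna_offsets[i] = vec

    group_idx = np.array([group_names.index(group_of[s]) for s in samples])
    mu = (baseline[:, None] * size_factors[None, :]
          * 2.0 ** mrna_offsets[:, group_idx])

    # NB(mean mu, var mu + alpha mu^2); near-zero alpha degenerates to Poisson
    a = alpha[:, None]
    with np.errstate(divide="ignore"):
        n_param = np.where(a > 1e-12, 1.0 / np.maximum(a, 1e-12), np.inf)
    p_param = n_param / (n_param + mu)
    counts = np.where(
        a > 1e-12,
        rng.negative_binomial(np.where(np.isfinite(n_param), n_param, 1.0),
                              np.clip(p_param, 1e-12, 1.0)),
        rng.poisson(mu),
    )

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=pd.Series(lengths, index=genes, name="length_bp"),
        groups=pd.Series(group_of, name="group"),
    )

    truth = pd.DataFrame({"gene_id": genes, "effect_class": classes}).set_index("gene_id")
    for num, den in CONTRASTS:
        if num not in group_names or den not in group_names:
            continue
        gi, gj = group_names.index(num), group_names.index(den)
        truth[f"lfc_{num}_vs_{den}"] = mrna_offsets[:, gi] - mrna_offsets[:, gj]
        truth[f"protein_lfc_{num}_vs_{den}"] = prot_offsets[:, gi] - prot_offsets[:, gj]
    truth["detected_as_protein"] = detected
    truth["protein_mode"] = modes
    truth["motif_planted"] = False
    truth.attrs["size_factors"] = pd.Series(size_factors, index=samples)
    truth.attrs["baseline_mean"] = pd.Series(baseline, index=genes)
    return cm, truth


def simulate_proteome(
    design: StudyDesign, counts: CountMatrix, truth: pd.DataFrame
) -> ProteinMatrix:
    """Reporter-intensity matrix for the detected-protein subset of genes.

    log2 intensity = protein baseline + planted group effect + batch
    log2-offset + N(0, sd). Samples are split into a "10-plex" batch (first
    10 samples) and a "16-plex" batch (the rest), with the 10-plex batch
    scaled globally by ``batch_ratio``. A ``missing_fraction`` of values is
    removed completely at random.
    """
    design.validate()
    rng = np.random.default_rng(_child_seed(design.seed, "proteome"))
    samples = list(counts.counts.columns)
    group_names = list(design.group_sizes)

    prot_genes = truth.index[truth["detected_as_protein"]].tolist()
    if not prot_genes:
        raise ValueError("no genes flagged detected_as_protein")

    # the 10-plex batch is spread evenly over the sample list so that the
    # kit batch is not confounded with the group factor
    n_batch_a = min(10, max(1, len(samples) - 1))
    a_idx = set(np.linspace(0, len(samples) - 1, n_batch_a).round().astype(int))
    batch = pd.Series(
        ["10-plex" if i in a_idx else "16-plex" for i in range(len(samples))],
        index=samples, name="batch",
    )

    base = rng.uniform(14.0, 20.0, len(prot_genes))
    group_idx = np.array([group_names.index(counts.groups[s]) for s in samples])
    prot_off = np.zeros((len(prot_genes), len(group_names)))
    # rebuild per-group protein offsets (YH is the reference, offset 0)
    for j, g in enumerate(group_names):
        if g == "YH":
            continue
        col = f"protein_lfc_{g}_vs_YH"
        if col in truth.columns:
            prot_off[:, j] = truth.loc[prot_genes, col].to_numpy()
    offs = prot_off[:, group_idx]

    log2_int = (
        base[:, None]
        + offs
        + rng.normal(0.0, design.protein_noise_sd, (len(prot_genes), len(samples)))
    )
    log2_int += np.where(batch.to_numpy() == "10-plex", np.log2(design.batch_ratio), 0.0)

    inten = 2.0 ** log2_int
    if design.missing_fraction > 0:
        mask = rng.random(inten.shape) < design.missing_fraction
        inten[mask] = np.nan

    return ProteinMatrix(
        intensities=pd.DataFrame(inten, index=prot_genes, columns=samples),
        batch=batch,
        groups=counts.groups.loc[samples],
    )


def simulate_promoters(
    truth: pd.DataFrame,
    pwm,
    length: int = 1000,
    seed: int = 0,
    base_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    target_class: str = "primary_down",
    planting_rate: float = 1.0,
) -> tuple[PromoterSet, pd.DataFrame]:
    """One promoter per gene, with motif instances planted in a target set.

    Background bases are i.i.d. from ``base_composition`` (A, C, G, T).
    Promoters of genes in ``target_class`` receive motif instances sampled
    from the PWM column distributions: ``floor(rate)`` guaranteed copies
    plus one more with probability ``rate - floor(rate)``. Returns the
    promoter set and a table of planted instances (gene, start, strand,
    sequence); ``truth['motif_planted']`` is updated in place.
    """
    if length < 100:
        raise ValueError("promoter length must be >= 100 bp")
    if pwm.width > length:
        raise ValueError("motif longer than promoter")
    comp = np.asarray(base_composition, dtype=float)
    if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9 or np.any(comp < 0):
        raise ValueError("base_composition must be 4 non-negative values summing to 1")

    rng = np.random.default_rng(_child_seed(seed, "promoters"))
    bases = np.array(list("ACGT"))
    genes = truth.index.tolist()
    seq_mat = rng.choice(4, size=(len(genes), length), p=comp)

    targets = set(truth.index[truth["effect_class"] == target_class])
    records = []
    whole = int(np.floor(planting_rate))
    frac = planting_rate - whole
    for i, g in enumerate(genes):
        if g not in targets:
            continue
        n_copies = whole + (1 if rng.random() < frac else 0)
        for _ in range(n_copies):
            inst = np.array([rng.choice(4, p=pwm.probs[j]) for j in range(pwm.width)])
            start = int(rng.integers(0, length - pwm.width + 1))
            seq_mat[i, start:start + pwm.width] = inst
            records.append(
                {"gene_id": g, "start": start, "strand": "+",
                 "sequence": "".join(bases[inst])}
            )
        if n_copies:
            truth.loc[g, "motif_planted"] = True

    seqs = {g: "".join(bases[seq_mat[i]]) for i, g in enumerate(genes)}
    planted = pd.DataFrame(records, columns=["gene_id", "start", "strand", "sequence"])
    return PromoterSet(seqs, role="foreground"), planted


@dataclass
class SimulatedStudy:
    """Bundle of all synthetic inputs generated from one design."""

    design: StudyDesign
    counts: CountMatrix
    truth: pd.DataFrame
    proteins: ProteinMatrix
    promoters: PromoterSet | None = None
    planted_sites: pd.DataFrame | None = None


def simulate_study(design: StudyDesign, pwm=None, promoter_length: int = 1000,
                   planting_rate: float = 1.0) -> SimulatedStudy:
    """Run all generators with child seeds derived from the design seed."""
    cm, truth = simulate_counts(design)
    prot = simulate_proteome(design, cm, truth)
    promoters = planted = None
    if pwm is not None:
        promoters, planted = simulate_promoters(
            truth, pwm, length=promoter_length, seed=design.seed,
            planting_rate=planting_rate,
        )
    return SimulatedStudy(design, cm, truth, prot, promoters, planted)


# ---------------------------------------------------------------------------
# fixture files


def write_fixtures(study: SimulatedStudy, directory: str | Path) -> Path:
    """Write all inputs as plain-text files plus a JSON manifest.

    The manifest records the full design, so ``regenerate_fixtures`` can
    rebuild every file byte-identically.
    """
    from . import io as asio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    asio.write_counts(study.counts, directory / "counts.tsv",
                      directory / "lengths.tsv")
    asio.write_sample_sheet(study.counts.groups, study.proteins.batch,
                            directory / "samples.tsv")
    asio.write_proteins(study.proteins, directory / "proteins.tsv")
    study.truth.reset_index().to_csv(directory / "truth.tsv", sep="\t", index=False)
    if study.promoters is not None:
        asio.write_fasta(study.promoters.sequences, directory / "promoters.fa")

    manifest = {
        "design": study.design.to_dict(),
        "files": {},
    }
    for f in sorted(directory.glob("*")):
        if f.name == "manifest.json":
            continue
        manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    # key order is preserved: group order in the design is meaningful
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def regenerate_fixtures(manifest_path: str | Path, directory: str | Path,
                        pwm=None) -> Path:
    """Re-run the generators from a manifest; files are byte-reproducible."""
    manifest = json.loads(Path(manifest_path).read_text())
    design = StudyDesign.from_dict(manifest["design"])
    study = simulate_study(design, pwm=pwm)
    return write_fixtures(study, directory)
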