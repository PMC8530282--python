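"""Synthetic isoform-switch data: annotation, usage proportions, NB counts.

The generator plants the signal regime the package is designed to detect:
*differential isoform usage with class-invariant gene totals*.  For each
effect gene, class 1 shifts a fixed fraction of usage mass from isoform 1
to isoform 2 while the gene's expected total expression is identical across
classes by construction — any learnable class signal therefore lives at the
exon/isoform level, not the gene level.

Each toy gene has ``isoforms_per_gene`` isoforms built from one private
exon per isoform plus ``parts_per_isoform - 1`` exons shared by all
isoforms, so every isoform contributes at least one private and one shared
exonic part.  Counts are negative binomial with variance ``mu + phi*mu^2``;
gene counts are emitted as the exact sum of the gene's isoform counts.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .annotation import (
    ExonicPart,
    GenomicInterval,
    RelationshipMatrix,
    TranscriptModel,
    build_gene_map,
    build_isoform_map,
    flatten_exonic_parts,
    write_parts_gtf,
)
from .preprocess import CountMatrix, SampleTable, write_matrix_tsv

import pandas as pd

__all__ = [
    "SyntheticSpec",
    "AnnotationBundle",
    "SyntheticDataset",
    "make_toy_annotation",
    "simulate_usage",
    "sample_counts",
    "generate",
    "export_dataset",
]

_EXON_LEN = 100
_EXON_GAP = 50
_GENE_SPACING = 100_000


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults define the study conditions."""

    n_genes: int = 60
    isoforms_per_gene: int = 2
    parts_per_isoform: int = 3
    n_per_class: int = 300
    n_effect_genes: int = 15
    switch_delta: float = 0.35
    nb_dispersion: float = 0.1  # variance = mu + phi * mu^2
    poisson: bool = False  # phi -> 0 limit
    baseline_log_mean: float = 4.0  # gene mean ~ exp(N(log_mean, log_sd))
    baseline_log_sd: float = 1.0
    library_scale_sd: float = 0.2  # per-sample lognormal scale, mean 1
    dirichlet_alpha: float = 5.0
    length_weight: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_effect_genes > self.n_genes:
            raise ValueError("n_effect_genes exceeds n_genes")
        if not 0 <= self.switch_delta <= 1:
            raise ValueError("switch_delta must be in [0, 1]")
        if self.isoforms_per_gene < 2:
            raise ValueError("need >= 2 isoforms per gene to switch usage")
        if self.parts_per_isoform < 2:
            raise ValueError(
                "parts_per_isoform < 2 cannot give each isoform both a "
                "private and a shared part"
            )
        if self.nb_dispersion <= 0 and not self.poisson:
            raise ValueError("nb_dispersion must be > 0 (or set poisson=True)")


@dataclass
class AnnotationBundle:
    transcripts: list[TranscriptModel]
    parts: list[ExonicPart]
    iso_map: RelationshipMatrix
    gene_map: RelationshipMatrix
    gene_ids: list[str]

    @property
    def part_ids(self) -> list[str]:
        return [p.part_id for p in self.parts]

    @property
    def transcript_ids(self) -> list[str]:
        return [t.transcript_id for t in self.transcripts]

    def transcript_gene(self) -> dict[str, str]:
        return {t.transcript_id: t.gene_id for t in self.transcripts}

    def part_gene(self) -> dict[str, str]:
        return {p.part_id: p.gene_id for p in self.parts}


@dataclass
class SyntheticDataset:
    annotation: AnnotationBundle
    exon_counts: CountMatrix
    isoform_counts: CountMatrix
    gene_counts: CountMatrix
    samples: SampleTable
    truth: dict = field(default_factory=dict)


def make_toy_annotation(spec: SyntheticSpec) -> AnnotationBundle:
    """Build toy genes whose isoforms share and privately own exonic parts.

    Gene *g* owns a disjoint genomic block; its exons are one private exon
    per isoform followed by the shared exons, each ``100`` bp with ``50`` bp
    gaps, so flattening yields one part per exon with the expected
    transcript sets.
    """
    transcripts: list[TranscriptModel] = []
    parts: list[ExonicPart] = []
    gene_ids: list[str] = []
    k = spec.isoforms_per_gene
    n_shared = spec.parts_per_isoform - 1
    for g in range(spec.n_genes):
        gene_id = f"G{g + 1:04d}"
        gene_ids.append(gene_id)
        offset = g * _GENE_SPACING + 1
        exons = [
            GenomicInterval(
                "chr1",
                offset + i * (_EXON_LEN + _EXON_GAP),
                offset + i * (_EXON_LEN + _EXON_GAP) + _EXON_LEN - 1,
                "+",
            )
            for i in range(k + n_shared)
        ]
        private, shared = exons[:k], exons[k:]
        gene_transcripts = [
            TranscriptModel(f"{gene_id}.T{j + 1}", gene_id, [private[j]] + shared)
            for j in range(k)
        ]
        transcripts.extend(gene_transcripts)
        parts.extend(flatten_exonic_parts(gene_transcripts))
    iso_map = build_isoform_map(parts, transcripts)
    gene_map = build_gene_map(parts, gene_ids)
    return AnnotationBundle(transcripts, parts, iso_map, gene_map, gene_ids)


def simulate_usage(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class isoform usage proportions and the effect-gene indices.

    Class 0 usage is symmetric Dirichlet(alpha); for effect genes class 1
    moves ``switch_delta`` of usage mass from isoform 1 to isoform 2.
    Returns ``(usage0, usage1, effect_idx)`` with usage arrays of shape
    (n_genes, isoforms_per_gene), each row summing to 1.
    """
    rng = rng or np.random.default_rng(spec.seed)
    k = spec.isoforms_per_gene
    usage0 = rng.dirichlet(np.full(k, spec.dirichlet_alpha), size=spec.n_genes)
    usage1 = usage0.copy()
    effect_idx = np.sort(
        rng.choice(spec.n_genes, size=spec.n_effect_genes, replace=False)
    )
    for g in effect_idx:
        moved = min(spec.switch_delta, usage0[g, 0])
        if moved < spec.switch_delta:
            warnings.warn(
                f"gene index {g}: only {moved:.3f} usage mass available to "
                f"shift (requested {spec.switch_delta})",
                stacklevel=2,
            )
        usage1[g, 0] = usage0[g, 0] - moved
        usage1[g, 1] = usage0[g, 1] + moved
    return usage0, usage1, effect_idx


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, phi: float, poisson: bool
) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if poisson or phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = 1.0 / (1.0 + phi * mean)
    return rng.negative_binomial(r, p)


def sample_counts(
    spec: SyntheticSpec,
    annotation: AnnotationBundle,
    usage: tuple[np.ndarray, np.ndarray, np.ndarray],
    rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Draw NB counts at exon, isoform and gene resolution from planted usage.

    Gene baseline means are log-normal (drawn once); isoform means are gene
    mean x class usage x per-sample library scale; exon-part means are the
    mask-weighted sum of isoform means.  Gene counts are the exact sum of
    isoform counts, so gene totals carry no usage signal.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    usage0, usage1, effect_idx = usage
    n_genes, k = usage0.shape
    if n_genes != spec.n_genes or k != spec.isoforms_per_gene:
        raise ValueError("usage shape inconsistent with spec")

    gene_mean = np.exp(
        rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=n_genes)
    )
    n = 2 * spec.n_per_class
    labels = np.r_[np.zeros(spec.n_per_class, int), np.ones(spec.n_per_class, int)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    libscale = np.exp(
        rng.normal(-spec.library_scale_sd**2 / 2, spec.library_scale_sd, size=n)
    )

    # isoform means: (n_iso, n_samples); isoform order matches annotation
    usage_by_class = np.stack([usage0, usage1])  # (2, n_genes, k)
    iso_gene = np.repeat(np.arange(n_genes), k)
    iso_usage = usage_by_class[:, iso_gene, np.tile(np.arange(k), n_genes)]  # (2, n_iso)
    iso_mean = (
        gene_mean[iso_gene][:, None] * iso_usage[labels, :].T * libscale[None, :]
    )
    iso_counts = _nb_draw(rng, iso_mean, spec.nb_dispersion, spec.poisson)

    R = annotation.iso_map.entries.astype(float)  # (n_parts, n_iso)
    if spec.length_weight:
        lengths = np.array([len(p.interval) for p in annotation.parts], float)
        R = R * (lengths / _EXON_LEN)[:, None]
    exon_mean = R @ iso_mean
    exon_counts = _nb_draw(rng, exon_mean, spec.nb_dispersion, spec.poisson)

    # gene counts: exact per-gene sum of isoform counts
    gene_counts = np.zeros((n_genes, n), dtype=iso_counts.dtype)
    np.add.at(gene_counts, iso_gene, iso_counts)

    # informative parts: expected mean differs between classes (libscale aside)
    class_iso_mean = gene_mean[iso_gene][None, :] * iso_usage  # (2, n_iso)
    class_exon_mean = class_iso_mean @ R.T  # (2, n_parts)
    diff = np.abs(class_exon_mean[1] - class_exon_mean[0])
    informative = diff > 1e-9 * np.maximum(class_exon_mean.max(axis=0), 1.0)

    part_ids = annotation.part_ids
    effect_genes = [annotation.gene_ids[g] for g in effect_idx]
    truth = {
        "effect_genes": effect_genes,
        "informative_exons": [p for p, inf in zip(part_ids, informative) if inf],
        "usage_class0": usage0.tolist(),
        "usage_class1": usage1.tolist(),
    }
    samples = SampleTable(
        pd.DataFrame({"label": labels}, index=pd.Index(sample_ids, name="sample_id"))
    )
    return SyntheticDataset(
        annotation=annotation,
        exon_counts=CountMatrix(part_ids, sample_ids, exon_counts, "exon"),
        isoform_counts=CountMatrix(
            annotation.transcript_ids, sample_ids, iso_counts, "isoform"
        ),
        gene_counts=CountMatrix(annotation.gene_ids, sample_ids, gene_counts, "gene"),
        samples=samples,
        truth=truth,
    )


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Full pipeline: annotation, planted usage, counts.  Seeded by the spec."""
    rng = np.random.default_rng(spec.seed)
    annotation = make_toy_annotation(spec)
    usage = simulate_usage(spec, rng)
    return sample_counts(spec, annotation, usage, rng)


def export_dataset(ds: SyntheticDataset, out_dir: str) -> dict[str, str]:
    """Write parts GTF, the three count TSVs, phenotype TSV and truth JSON."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "parts_gtf": os.path.join(out_dir, "parts.gtf"),
        "exon_counts": os.path.join(out_dir, "exon_counts.tsv"),
        "isoform_counts": os.path.join(out_dir, "isoform_counts.tsv"),
        "gene_counts": os.path.join(out_dir, "gene_counts.tsv"),
        "phenotype": os.path.join(out_dir, "phenotype.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_parts_gtf(ds.annotation.parts, paths["parts_gtf"])
    write_matrix_tsv(ds.exon_counts, paths["exon_counts"])
    write_matrix_tsv(ds.isoform_counts, paths["isoform_counts"])
    write_matrix_tsv(ds.gene_counts, paths["gene_counts"])
    ds.samples.frame.to_csv(paths["phenotype"], sep="\t", index_label="sample_id")
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=1)
    return paths
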