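"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from isomapnet.annotation import GenomicInterval, TranscriptModel

# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; never share code with the package)


def per_base_parts(transcripts):
    """Brute-force exonic-part oracle: label every base with its covering set.

    Returns a list of (chrom, strand, start, end, frozenset_of_transcripts)
    tuples sorted by (chrom, strand, start).
    """
    cover: dict[tuple[str, str, int], set[str]] = {}
    for tm in transcripts:
        for e in tm.exons:
            for b in range(e.start, e.end + 1):
                cover.setdefault((e.chrom, e.strand, b), set()).add(tm.transcript_id)
    runs = []
    for (chrom, strand, b), tids in sorted(cover.items()):
        key = frozenset(tids)
        if runs and runs[-1][0] == chrom and runs[-1][1] == strand \
                and runs[-1][3] == b - 1 and runs[-1][4] == key:
            runs[-1][3] = b
        else:
            runs.append([chrom, strand, b, b, key])
    return [(c, s, lo, hi, k) for c, s, lo, hi, k in runs]


def containment_oracle(part, transcript) -> bool:
    """True iff every base of the part lies inside the transcript's exon union."""
    bases = set()
    for e in transcript.exons:
        if e.chrom == part.interval.chrom and e.strand == part.interval.strand:
            bases.update(range(e.start, e.end + 1))
    return all(b in bases for b in range(part.interval.start, part.interval.end + 1))


def random_gene(rng: np.random.Generator, gene_id: str, max_exons: int = 4):
    """A random small gene: 1-4 transcripts of 1-max_exons disjoint exons."""
    transcripts = []
    for t in range(rng.integers(1, 5)):
        cursor = int(rng.integers(1, 200))
        exons = []
        for _ in range(rng.integers(1, max_exons + 1)):
            length = int(rng.integers(5, 120))
            exons.append(GenomicInterval("chr1", cursor, cursor + length - 1, "+"))
            cursor += length + int(rng.integers(1, 80))
        transcripts.append(TranscriptModel(f"{gene_id}.T{t + 1}", gene_id, exons))
    return transcripts


def tmm_reference(counts: np.ndarray, logratio_trim=0.3, sum_trim=0.05) -> np.ndarray:
    """Literal independent transcription of the TMM definition (loop-based).

    Reference sample: 75th-percentile-CPM closest to the mean; per sample,
    two-sided trimming of M by rank and A by rank, precision-weighted mean M.
    Shares no code with the package implementation.
    """
    counts = np.asarray(counts, dtype=float)
    nf, ns = counts.shape
    lib = counts.sum(axis=0)
    q75 = np.array([np.quantile(counts[:, j], 0.75) / lib[j] for j in range(ns)])
    ref_j = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.ones(ns)
    for j in range(ns):
        ms, as_, ws = [], [], []
        for i in range(nf):
            o, r = counts[i, j], counts[i, ref_j]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref_j]
                ms.append(np.log2(po / pr))
                as_.append(0.5 * np.log2(po * pr))
                ws.append((lib[j] - o) / (lib[j] * o) + (lib[ref_j] - r) / (lib[ref_j] * r))
        ms, as_, ws = map(np.array, (ms, as_, ws))
        if ms.size == 0 or np.max(np.abs(ms)) < 1e-6:
            continue
        n = ms.size
        # rank with average ties, computed naively
        def avranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(n)
            i = 0
            sv = v[order]
            while i < n:
                k = i
                while k + 1 < n and sv[k + 1] == sv[i]:
                    k += 1
                ranks[order[i : k + 1]] = (i + k) / 2 + 1
                i = k + 1
            return ranks
        rm, ra = avranks(ms), avranks(as_)
        lo_l = np.floor(n * logratio_trim) + 1
        hi_l = n + 1 - lo_l
        lo_s = np.floor(n * sum_trim) + 1
        hi_s = n + 1 - lo_s
        keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
        if keep.any():
            f = np.sum(ms[keep] / ws[keep]) / np.sum(1.0 / ws[keep])
            factors[j] = 2.0 ** f
    return factors / np.exp(np.mean(np.log(factors)))


def auc_by_enumeration(scores, labels) -> float:
    """O(n^2) Mann-Whitney AUC: all (pos, neg) pairs, ties half credit."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def toy_gtf(tmp_path_factory):
    """GTF with 3 genes / 7 transcripts, both attribute dialects."""
    lines = []
    tx_per_gene = {"G1": 3, "G2": 2, "G3": 2}
    start = 1000
    for gi, (gid, ntx) in enumerate(tx_per_gene.items()):
        lines.append(
            f"chr1\tsrc\tgene\t{start}\t{start + 5000}\t.\t+\t.\t"
            f'gene_id "{gid}";'
        )
        for t in range(1, ntx + 1):
            tid = f"{gid}.T{t}"
            for e in range(2):
                lo = start + t * 300 + e * 150
                hi = lo + 99
                if gi == 2:  # exercise the key=value dialect
                    attrs = f"gene_id={gid};transcript_id={tid}"
                else:
                    attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                lines.append(f"chr1\tsrc\texon\t{lo}\t{hi}\t.\t+\t.\t{attrs}")
        start += 100_000
    path = tmp_path_factory.mktemp("gtf") / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic isoform-switch dataset shared across tests."""
    from isomapnet.synthetic import SyntheticSpec, generate

    return generate(SyntheticSpec(n_genes=12, n_effect_genes=4, n_per_class=60, seed=11))
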