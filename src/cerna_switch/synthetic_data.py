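"""Synthetic study generator with planted ground truth.

Emulates the statistical structure the downstream analysis assumes: a
two-condition (contractile vs stent-injury) RNA-seq design with three
replicates per condition; negative-binomial counts with log-normal baseline
means and gamma-distributed per-gene dispersions; planted differential
expression; planted ceRNA axes whose members share a per-sample latent
factor (the miRNA loading with opposite sign) so that their expression is
correlated; FPKM derived from the simulated counts with the true spliced
lengths; a toy genome in which planted cis pairs fall within the 100 kb
window and decoy pairs just outside; transcript sequences with or without
planted open reading frames and with planted complementary pairing sites;
miRNA-target and protein-protein interaction tables seeded with the planted
structure plus uniform decoys; and a gene-set collection with two signal
sets.

Everything is drawn from one seeded generator in a fixed order, so a given
config + seed reproduces the study byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as iof
from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    InteractionTable,
    PPITable,
    TranscriptModel,
)
from .lncrna_discovery import fickett_score

__all__ = ["SimulationConfig", "GroundTruth", "StudyData", "simulate",
           "write_study", "read_study"]

LN2 = float(np.log(2.0))
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for :func:`simulate`. Defaults are the conditions
    the package's own acceptance suite runs under (a scaled-down
    transcriptome; see docs/methods.md)."""

    n_mRNA: int = 1000
    n_lncRNA: int = 300
    n_miRNA: int = 80
    replicates: int = 3
    baseline_meanlog: float = 5.0
    baseline_sdlog: float = 1.0
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.05  # gamma mean 0.1
    de_fraction_mRNA: float = 0.08
    de_fraction_lncRNA: float = 0.10
    de_fraction_miRNA: float = 0.15
    de_log2fc_low: float = 2.0
    de_log2fc_high: float = 4.0
    axis_log2fc_low: float = 3.0
    axis_log2fc_high: float = 5.0
    n_planted_axes: int = 8
    n_planted_cis: int = 8
    rho: float = 0.9
    decoy_edge_multiplier: int = 5
    known_lnc_fraction: float = 0.3
    single_exon_fraction: float = 0.08
    short_fraction: float = 0.05
    coding_candidate_fraction: float = 0.08
    overlap_coding_fraction: float = 0.05
    low_expression_fraction: float = 0.05
    depth_sdlog: float = 0.1
    mrna_len_low: int = 500
    mrna_len_high: int = 900
    lnc_len_low: int = 300
    lnc_len_high: int = 600
    mirna_len: int = 22
    site_len: int = 30
    site_gc: float = 0.9
    ppi_decoy_per_mrna: float = 2.0
    n_gene_sets: int = 20
    n_signal_sets: int = 2
    n_chromosomes: int = 6
    control_label: str = "contractile"
    treated_label: str = "stent"
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_mRNA, self.n_lncRNA, self.n_miRNA) < 1:
            raise ValueError("all gene counts must be >= 1")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        for name in ("de_fraction_mRNA", "de_fraction_lncRNA", "de_fraction_miRNA"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        n_candidates = self.n_lncRNA - round(self.known_lnc_fraction * self.n_lncRNA)
        if self.n_planted_axes > min(self.n_mRNA, self.n_lncRNA, self.n_miRNA):
            raise ValueError(
                f"{self.n_planted_axes} planted axes exceed available genes"
            )
        if self.n_planted_cis > min(self.n_mRNA, self.n_lncRNA):
            raise ValueError("more planted cis pairs than available genes")


@dataclass
class GroundTruth:
    de_genes: dict[str, float]  # gene -> true log2FC
    planted_axes: list[tuple[str, str, str]]  # (lncRNA, miRNA, mRNA)
    planted_cis_pairs: list[tuple[str, str, int]]  # (lncRNA, gene, distance)
    coding_labels: dict[str, str]  # transcript -> coding | noncoding
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "de_genes": self.de_genes,
                "planted_axes": [list(a) for a in self.planted_axes],
                "planted_cis_pairs": [list(p) for p in self.planted_cis_pairs],
                "coding_labels": self.coding_labels,
            },
            sort_keys=True,
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            de_genes=d["de_genes"],
            planted_axes=[tuple(a) for a in d["planted_axes"]],
            planted_cis_pairs=[tuple(p) for p in d["planted_cis_pairs"]],
            coding_labels=d["coding_labels"],
            seed=d.get("seed", 0),
        )


@dataclass
class StudyData:
    config: SimulationConfig
    counts: ExpressionMatrix
    fpkm: ExpressionMatrix
    transcripts: list[TranscriptModel]
    sequences: dict[str, str]
    mi_mrna: InteractionTable
    mi_lnc: InteractionTable
    ppi: PPITable
    gene_sets: GeneSetCollection
    truth: GroundTruth


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    bases = rng.choice(list("ACGT"), size=n, p=[p_at, p_gc, p_gc, p_at])
    return "".join(bases)


def _strip_orfs(seq: str) -> str:
    """Remove every ATG so no ORF can start (G -> C cannot re-create one)."""
    while "ATG" in seq:
        i = seq.index("ATG")
        seq = seq[: i + 2] + "C" + seq[i + 3 :]
    return seq


def _noncoding_seq(rng: np.random.Generator, n: int) -> str:
    for _ in range(50):
        seq = _strip_orfs(_random_seq(rng, n))
        if n < 200 or fickett_score(seq) < 0.95:
            return seq
    raise RuntimeError("could not draw a noncoding sequence")  # pragma: no cover


def _coding_seq(rng: np.random.Generator, n: int) -> tuple[str, int, int]:
    """Random sequence with one planted ORF; returns (seq, orf_start, orf_end)."""
    utr5 = 60
    orf_nt = min(int(n * 0.5), n - utr5 - 60)
    orf_nt = max(300, orf_nt - orf_nt % 3)
    if utr5 + orf_nt + 30 > n:
        raise ValueError(f"sequence of {n} nt too short for a planted ORF")
    n_codons = orf_nt // 3 - 2
    body = "".join(rng.choice(_CODONS, size=n_codons))
    orf = "ATG" + body + "TAA"
    utr3 = n - utr5 - len(orf)
    seq = (
        _strip_orfs(_random_seq(rng, utr5))
        + orf
        + _strip_orfs(_random_seq(rng, utr3))
    )
    return seq, utr5, utr5 + len(orf)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _split_lengths(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    if parts == 1:
        return [total]
    raw = rng.multinomial(total - parts, [1.0 / parts] * parts)
    return [int(x) + 1 for x in raw]


def simulate(config: SimulationConfig = SimulationConfig()) -> StudyData:
    """Generate a complete synthetic study with its ground-truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    c = config

    mrna_ids = [f"mRNA_{i:04d}" for i in range(1, c.n_mRNA + 1)]
    lnc_ids = [f"lnc_{i:04d}" for i in range(1, c.n_lncRNA + 1)]
    mir_ids = [f"mir_{i:04d}" for i in range(1, c.n_miRNA + 1)]
    all_ids = mrna_ids + lnc_ids + mir_ids
    gene_class = pd.Series(
        ["mRNA"] * c.n_mRNA + ["lncRNA"] * c.n_lncRNA + ["miRNA"] * c.n_miRNA,
        index=all_ids,
    )

    # --- lncRNA sub-populations -------------------------------------------
    n_known = round(c.known_lnc_fraction * c.n_lncRNA)
    known_lncs = lnc_ids[:n_known]
    candidates = lnc_ids[n_known:]
    n_cand = len(candidates)
    n_single = round(c.single_exon_fraction * n_cand)
    n_short = round(c.short_fraction * n_cand)
    n_codingc = round(c.coding_candidate_fraction * n_cand)
    n_overlap = round(c.overlap_coding_fraction * n_cand)
    n_lowexp = round(c.low_expression_fraction * n_cand)
    cursor = 0
    single_exon = candidates[cursor : cursor + n_single]; cursor += n_single
    short_cands = candidates[cursor : cursor + n_short]; cursor += n_short
    coding_cands = candidates[cursor : cursor + n_codingc]; cursor += n_codingc
    overlap_cands = candidates[cursor : cursor + n_overlap]; cursor += n_overlap
    lowexp_cands = candidates[cursor : cursor + n_lowexp]; cursor += n_lowexp
    clean_cands = candidates[cursor:]
    if len(clean_cands) < c.n_planted_axes:
        raise ValueError("not enough clean candidate lncRNAs for planted axes")

    # --- planted axes ------------------------------------------------------
    half = c.n_planted_axes // 2
    axis_lncs = list(known_lncs[:half]) + list(clean_cands[: c.n_planted_axes - half])
    if len(axis_lncs) < c.n_planted_axes:  # few known lncs configured
        axis_lncs = list(clean_cands[: c.n_planted_axes])
    axis_mirs = mir_ids[: c.n_planted_axes]
    axis_mrnas = mrna_ids[: c.n_planted_axes]
    axes = list(zip(axis_lncs, axis_mirs, axis_mrnas))
    axis_pattern_up = rng.random(c.n_planted_axes) < 0.5  # True: lnc/mRNA up

    # --- true log2FC -------------------------------------------------------
    true_lfc = pd.Series(0.0, index=all_ids)
    for k, (L, mu, M) in enumerate(axes):
        mag = rng.uniform(c.axis_log2fc_low, c.axis_log2fc_high, size=3)
        sign = 1.0 if axis_pattern_up[k] else -1.0
        true_lfc[L] = sign * mag[0]
        true_lfc[mu] = -sign * mag[1]
        true_lfc[M] = sign * mag[2]
    axis_members = {g for axis in axes for g in axis}

    # planted cis pairs (selected here so both members can be planted DE;
    # the genomic placement below puts each pair within the 100 kb window)
    cis_lncs = [g for g in clean_cands[c.n_planted_axes :]][: c.n_planted_cis]
    if len(cis_lncs) < c.n_planted_cis:
        cis_lncs = (cis_lncs + [g for g in known_lncs if g not in axis_members])[
            : c.n_planted_cis
        ]
    cis_mrnas = mrna_ids[c.n_planted_axes : c.n_planted_axes + c.n_planted_cis]
    for g in cis_lncs + cis_mrnas:
        if true_lfc[g] == 0.0:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            true_lfc[g] = sign * rng.uniform(c.axis_log2fc_low, c.axis_log2fc_high)
    planted_ids = axis_members | set(cis_lncs) | set(cis_mrnas)

    for ids, frac in (
        (mrna_ids, c.de_fraction_mRNA),
        (lnc_ids, c.de_fraction_lncRNA),
        (mir_ids, c.de_fraction_miRNA),
    ):
        pool = [g for g in ids if g not in planted_ids and g not in lowexp_cands]
        n_de = round(frac * len(ids))
        chosen = rng.choice(pool, size=min(n_de, len(pool)), replace=False)
        mags = rng.uniform(c.de_log2fc_low, c.de_log2fc_high, size=len(chosen))
        signs = np.where(rng.random(len(chosen)) < 0.5, 1.0, -1.0)
        for g, m, s in zip(chosen, mags, signs):
            true_lfc[g] = s * m
    de_genes = {g: float(v) for g, v in true_lfc.items() if v != 0.0}

    # --- transcript structures --------------------------------------------
    spliced_len: dict[str, int] = {}
    n_exons: dict[str, int] = {}
    for g in mrna_ids:
        spliced_len[g] = int(rng.integers(c.mrna_len_low, c.mrna_len_high + 1))
        n_exons[g] = int(rng.integers(3, 9))
    for g in lnc_ids:
        spliced_len[g] = int(rng.integers(c.lnc_len_low, c.lnc_len_high + 1))
        n_exons[g] = int(rng.integers(2, 5))
    for g in coding_cands:  # needs room for a planted >= 300 nt ORF
        spliced_len[g] = max(spliced_len[g], 460)
    for g in single_exon:
        n_exons[g] = 1
    for g in short_cands:
        spliced_len[g] = int(rng.integers(120, 181))
    for g in mir_ids:
        spliced_len[g] = c.mirna_len
        n_exons[g] = 1

    # --- genome placement --------------------------------------------------
    chroms = [f"chr{i}" for i in range(1, c.n_chromosomes + 1)]
    cis_gaps = rng.integers(1_000, 90_000, size=c.n_planted_cis)
    n_decoy_cis = 2
    decoy_cis_lncs = [g for g in clean_cands if g not in set(cis_lncs)][
        c.n_planted_axes : c.n_planted_axes + n_decoy_cis
    ]
    start_m = c.n_planted_axes + c.n_planted_cis
    decoy_cis_mrnas = mrna_ids[start_m : start_m + n_decoy_cis]
    decoy_cis_gaps = 100_000 + rng.integers(1, 5_000, size=n_decoy_cis)

    paired_ids = set(cis_lncs) | set(cis_mrnas) | set(decoy_cis_lncs) | set(
        decoy_cis_mrnas
    ) | set(overlap_cands)
    overlap_hosts = mrna_ids[-len(overlap_cands):] if overlap_cands else []
    paired_ids |= set(overlap_hosts)

    units: list[tuple] = []
    for L, M, gap in zip(cis_lncs, cis_mrnas, cis_gaps):
        units.append(("pair", L, M, int(gap)))
    for L, M, gap in zip(decoy_cis_lncs, decoy_cis_mrnas, decoy_cis_gaps):
        units.append(("pair", L, M, int(gap)))
    for host, cand in zip(overlap_hosts, overlap_cands):
        units.append(("overlap", host, cand))
    for g in all_ids:
        if g not in paired_ids:
            units.append(("single", g))

    cursors = {ch: 50_000 for ch in chroms}
    placements: dict[str, tuple[str, str, int]] = {}  # id -> (chrom, strand, start)
    span: dict[str, tuple[int, int]] = {}
    exon_map: dict[str, list[tuple[int, int]]] = {}

    def build_exons(g: str, chrom: str, strand: str, start: int) -> int:
        k = n_exons[g]
        ex_lens = _split_lengths(rng, spliced_len[g], k)
        introns = rng.integers(200, 2_001, size=max(k - 1, 1))
        pos = start
        exons = []
        for j, el in enumerate(ex_lens):
            exons.append((pos, pos + el - 1))
            pos = pos + el + (int(introns[j]) if j < k - 1 else 0)
        exon_map[g] = exons
        span[g] = (exons[0][0], exons[-1][1])
        placements[g] = (chrom, strand, exons[0][0])
        return exons[-1][1]

    for u_idx, unit in enumerate(units):
        chrom = chroms[u_idx % len(chroms)]
        cursors[chrom] += int(rng.integers(110_000, 300_000))
        start = cursors[chrom]
        if unit[0] == "single":
            g = unit[1]
            strand = "+" if rng.random() < 0.5 else "-"
            end = build_exons(g, chrom, strand, start)
        elif unit[0] == "pair":
            _, L, M, gap = unit
            strand = "+" if rng.random() < 0.5 else "-"
            end_l = build_exons(L, chrom, strand, start)
            strand_m = "+" if rng.random() < 0.5 else "-"
            end = build_exons(M, chrom, strand_m, end_l + gap)
        else:  # overlap: candidate copies the host's exons, same strand
            _, host, cand = unit
            strand = "+" if rng.random() < 0.5 else "-"
            end = build_exons(host, chrom, strand, start)
            exon_map[cand] = list(exon_map[host])
            span[cand] = span[host]
            placements[cand] = placements[host]
            spliced_len[cand] = spliced_len[host]
            n_exons[cand] = n_exons[host]
        cursors[chrom] = end

    # --- expression --------------------------------------------------------
    n_rep = c.replicates
    samples = [f"Cont_{i}" for i in range(1, n_rep + 1)] + [
        f"Stent_{i}" for i in range(1, n_rep + 1)
    ]
    condition = pd.Series(
        [c.control_label] * n_rep + [c.treated_label] * n_rep, index=samples
    )
    treated_mask = np.array([0.0] * n_rep + [1.0] * n_rep)

    base = rng.lognormal(c.baseline_meanlog, c.baseline_sdlog, size=len(all_ids))
    base = pd.Series(base, index=all_ids)
    for g in lowexp_cands:
        base[g] = 0.01
    alpha = rng.gamma(c.dispersion_shape, c.dispersion_scale, size=len(all_ids))
    alpha = pd.Series(np.maximum(alpha, 1e-4), index=all_ids)

    # latent factor loading: the correlation the analysis measures between
    # axis members is the pooled-sample Pearson r on log2 FPKM, to which the
    # shared condition effect (both members differentially expressed in the
    # same direction) already contributes ~ (lfc/2)^2 of shared log2
    # variance against a counting-noise floor sigma2. lambda tops the factor
    # up only as far as needed to reach rho in expectation; with the default
    # planted fold changes the condition effect alone exceeds rho = 0.9 and
    # lambda is 0.
    sigma2 = (1.0 / np.exp(c.baseline_meanlog) + float(alpha.mean())) / LN2**2
    if c.rho > 0:
        d_shared = ((c.axis_log2fc_low + c.axis_log2fc_high) / 4.0) ** 2
        lam2 = max(0.0, (c.rho * (d_shared + sigma2) - d_shared) / (1.0 - c.rho))
        lam = float(np.sqrt(lam2))
    else:
        lam = 0.0
    loading = pd.Series(0.0, index=all_ids)
    for (L, mu, M) in axes:
        loading[L] = lam
        loading[M] = lam
        loading[mu] = -lam

    f_s = rng.standard_normal(len(samples))
    depth = rng.lognormal(0.0, c.depth_sdlog, size=len(samples))
    mean = (
        base.to_numpy()[:, None]
        * np.power(2.0, true_lfc.to_numpy()[:, None] * treated_mask[None, :])
        * np.power(2.0, loading.to_numpy()[:, None] * f_s[None, :])
        * depth[None, :]
    )
    r_param = 1.0 / alpha.to_numpy()[:, None]
    p_param = r_param / (r_param + mean)
    counts = rng.negative_binomial(r_param, p_param)
    counts_df = pd.DataFrame(counts, index=all_ids, columns=samples)

    lengths_kb = pd.Series({g: spliced_len[g] / 1_000.0 for g in all_ids})
    lib_m = counts_df.sum(axis=0) / 1.0e6
    fpkm_df = counts_df.div(lib_m, axis=1).div(lengths_kb[all_ids].to_numpy(), axis=0)

    counts_em = ExpressionMatrix(counts_df, condition, gene_class, unit="counts")
    fpkm_em = ExpressionMatrix(fpkm_df, condition, gene_class, unit="FPKM")

    # --- sequences ---------------------------------------------------------
    sequences: dict[str, str] = {}
    orf_bounds: dict[str, tuple[int, int]] = {}
    coding_labels: dict[str, str] = {}
    for g in mrna_ids:
        seq, o0, o1 = _coding_seq(rng, spliced_len[g])
        sequences[g] = seq
        orf_bounds[g] = (o0, o1)
        coding_labels[g] = "coding"
    for g in lnc_ids:
        if g in coding_cands or g in overlap_cands:
            sequences[g], _, _ = _coding_seq(rng, spliced_len[g])
            coding_labels[g] = "coding"
        else:
            sequences[g] = _noncoding_seq(rng, spliced_len[g])
            coding_labels[g] = "noncoding"
    for g in mir_ids:
        sequences[g] = _random_seq(rng, c.mirna_len)

    # planted complementary pairing sites (GC-biased, in the mRNA 3' UTR)
    for (L, mu, M) in axes:
        site = _random_seq(rng, c.site_len, gc=c.site_gc)
        lseq = sequences[L]
        pos_l = int(rng.integers(0, len(lseq) - c.site_len + 1))
        lseq = lseq[:pos_l] + site + lseq[pos_l + c.site_len :]
        sequences[L] = _strip_orfs(lseq)
        mseq = sequences[M]
        o0, o1 = orf_bounds[M]
        lo, hi = o1, len(mseq) - c.site_len
        pos_m = int(rng.integers(lo, hi + 1)) if hi >= lo else len(mseq) - c.site_len
        rc = _revcomp(sequences[L][pos_l : pos_l + c.site_len])
        sequences[M] = mseq[:pos_m] + rc + mseq[pos_m + c.site_len :]

    # --- transcript models -------------------------------------------------
    biotype = {}
    for g in mrna_ids:
        biotype[g] = "protein_coding"
    for g in known_lncs:
        biotype[g] = "known_lncRNA"
    for g in candidates:
        biotype[g] = "lncRNA_candidate"
    for g in mir_ids:
        biotype[g] = "miRNA"
    transcripts = []
    for g in all_ids:
        chrom, strand, _ = placements[g]
        s, e = span[g]
        transcripts.append(
            TranscriptModel(
                transcript_id=g,
                gene_id=g,
                chromosome=chrom,
                strand=strand,
                start=s,
                end=e,
                exons=list(exon_map[g]),
                biotype=biotype[g],
                sequence=sequences[g],
            )
        )

    # --- interaction tables ------------------------------------------------
    sources = sorted(iof.INTERACTION_SOURCES)

    def planted_rows(pairs: list[tuple[str, str]]) -> list[tuple[str, str, str]]:
        rows = []
        for (m, t) in pairs:
            n_src = int(rng.integers(1, 4))
            for s in rng.choice(sources, size=n_src, replace=False):
                rows.append((m, t, str(s)))
        return rows

    def decoy_rows(
        targets: list[str], existing: set[tuple[str, str]], n: int
    ) -> list[tuple[str, str, str]]:
        rows = []
        seen = set(existing)
        guard = 0
        while len(rows) < n and guard < 50 * n:
            guard += 1
            m = mir_ids[int(rng.integers(len(mir_ids)))]
            t = targets[int(rng.integers(len(targets)))]
            if (m, t) in seen:
                continue
            seen.add((m, t))
            rows.append((m, t, str(rng.choice(sources))))
        return rows

    mi_m_pairs = [(mu, M) for (L, mu, M) in axes]
    mi_l_pairs = [(mu, L) for (L, mu, M) in axes]
    mi_m_rows = planted_rows(mi_m_pairs)
    mi_m_rows += decoy_rows(
        mrna_ids, set(mi_m_pairs), c.decoy_edge_multiplier * len(mi_m_pairs)
    )
    mi_l_rows = planted_rows(mi_l_pairs)
    mi_l_rows += decoy_rows(
        lnc_ids, set(mi_l_pairs), c.decoy_edge_multiplier * len(mi_l_pairs)
    )
    mi_mrna = InteractionTable(
        pd.DataFrame(mi_m_rows, columns=["miRNA", "target", "source"])
    )
    mi_lnc = InteractionTable(
        pd.DataFrame(mi_l_rows, columns=["miRNA", "target", "source"])
    )

    # --- PPI table ---------------------------------------------------------
    ppi_rows = []
    for i in range(len(axis_mrnas)):
        for j in range(i + 1, len(axis_mrnas)):
            ppi_rows.append(
                (axis_mrnas[i], axis_mrnas[j], float(rng.uniform(0.6, 0.95)))
            )
    n_decoy_ppi = int(c.ppi_decoy_per_mrna * c.n_mRNA)
    seen_pairs = {(a, b) for a, b, _ in ppi_rows}
    added = 0
    guard = 0
    while added < n_decoy_ppi and guard < 50 * n_decoy_ppi:
        guard += 1
        a, b = rng.choice(mrna_ids, size=2, replace=False)
        a, b = (a, b) if a < b else (b, a)
        if (a, b) in seen_pairs:
            continue
        seen_pairs.add((a, b))
        ppi_rows.append((a, b, float(rng.uniform(0.1, 0.95))))
        added += 1
    ppi = PPITable(
        pd.DataFrame(ppi_rows, columns=["protein_a", "protein_b", "combined_score"])
    )

    # --- gene sets ---------------------------------------------------------
    de_mrnas = [g for g in mrna_ids if true_lfc[g] != 0.0]
    sets: dict[str, list[str]] = {}
    for i in range(c.n_signal_sets):
        size = int(rng.integers(15, 41))
        n_sig = min(int(0.7 * size), len(de_mrnas))
        members = list(rng.choice(de_mrnas, size=n_sig, replace=False))
        others = [g for g in mrna_ids if g not in set(members)]
        members += list(rng.choice(others, size=size - n_sig, replace=False))
        sets[f"SIGNAL_SET_{i + 1:02d}"] = sorted(members)
    for i in range(c.n_gene_sets - c.n_signal_sets):
        size = int(rng.integers(15, 41))
        sets[f"RANDOM_SET_{i + 1:02d}"] = sorted(
            rng.choice(mrna_ids, size=size, replace=False)
        )
    gene_sets = GeneSetCollection(sets, universe=list(mrna_ids))

    truth = GroundTruth(
        de_genes=de_genes,
        planted_axes=axes,
        planted_cis_pairs=[
            (L, M, int(g)) for L, M, g in zip(cis_lncs, cis_mrnas, cis_gaps)
        ],
        coding_labels=coding_labels,
        seed=c.seed,
    )
    return StudyData(
        config=c,
        counts=counts_em,
        fpkm=fpkm_em,
        transcripts=transcripts,
        sequences=sequences,
        mi_mrna=mi_mrna,
        mi_lnc=mi_lnc,
        ppi=ppi,
        gene_sets=gene_sets,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# persistence


def write_study(directory: str | Path, study: StudyData) -> Path:
    """Write every study file in the io_formats dialects plus the manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    iof.write_expression(study.counts, d / "counts.tsv")
    iof.write_expression(study.fpkm, d / "fpkm.tsv")
    design = pd.DataFrame(
        {
            "sample": study.counts.samples,
            "condition": [
                study.counts.sample_condition[s] for s in study.counts.samples
            ],
        }
    )
    design.to_csv(d / "design.tsv", sep="\t", index=False)
    classes = pd.DataFrame(
        {
            "gene_id": list(study.counts.values.index),
            "rna_class": study.counts.gene_class[study.counts.values.index],
        }
    )
    classes.to_csv(d / "gene_classes.tsv", sep="\t", index=False)
    iof.write_gtf(study.transcripts, d / "annot.gtf")
    iof.write_fasta(study.sequences, d / "tx.fa")
    mi = study.mi_mrna.edges.copy()
    mi["target_class"] = "mRNA"
    ml = study.mi_lnc.edges.copy()
    ml["target_class"] = "lncRNA"
    pd.concat([mi, ml], ignore_index=True).to_csv(
        d / "mirna_targets.tsv", sep="\t", index=False
    )
    study.ppi.edges.to_csv(d / "ppi.tsv", sep="\t", index=False)
    iof.write_gmt(study.gene_sets, d / "sets.gmt")
    (d / "truth.json").write_text(study.truth.to_json())
    (d / "config.json").write_text(
        json.dumps(dataclasses.asdict(study.config), sort_keys=True, indent=1)
    )
    return d


def read_study(directory: str | Path) -> StudyData:
    """Load a written study back through the io_formats readers."""
    d = Path(directory)
    config = SimulationConfig(**json.loads((d / "config.json").read_text()))
    design = iof.read_design(d / "design.tsv")
    classes = pd.read_csv(d / "gene_classes.tsv", sep="\t").set_index("gene_id")[
        "rna_class"
    ]
    counts = iof.read_counts(d / "counts.tsv", design, classes)
    fpkm = iof.read_fpkm(d / "fpkm.tsv", design, classes)
    transcripts = iof.read_gtf(d / "annot.gtf")
    sequences = iof.read_fasta(d / "tx.fa")
    for t in transcripts:
        t.sequence = sequences.get(t.transcript_id)
    targets = pd.read_csv(d / "mirna_targets.tsv", sep="\t", dtype=str)
    mi_mrna = InteractionTable(
        targets[targets["target_class"] == "mRNA"][
            ["miRNA", "target", "source"]
        ].reset_index(drop=True)
    )
    mi_lnc = InteractionTable(
        targets[targets["target_class"] == "lncRNA"][
            ["miRNA", "target", "source"]
        ].reset_index(drop=True)
    )
    ppi = iof.read_ppi(d / "ppi.tsv")
    gene_sets = iof.read_gmt(d / "sets.gmt")
    gene_sets.universe = [g for g in counts.values.index if classes[g] == "mRNA"]
    truth = GroundTruth.from_json((d / "truth.json").read_text())
    return StudyData(
        config=config,
        counts=counts,
        fpkm=fpkm,
        transcripts=transcripts,
        sequences=sequences,
        mi_mrna=mi_mrna,
        mi_lnc=mi_lnc,
        ppi=ppi,
        gene_sets=gene_sets,
        truth=truth,
    )
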