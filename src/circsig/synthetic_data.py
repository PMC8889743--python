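"""Synthetic paired tumor/normal cohorts with planted ground truth.

The generator emulates the structure of a seven-tissue, paired tumor/normal
circRNA sequencing study: per-sample back-spliced and forward-spliced
junction counts drawn from negative binomial distributions around
tissue/condition means, matched gene-level FPKM and raw counts, a toy gene
annotation (exons, CDS, flanking introns) consistent with the circRNA
records, and a truth table recording every planted effect.

Planted effect classes (one per circRNA):

* ``tissue_specific`` — mean elevated ``tissue_effect``-fold in one tissue,
  zero everywhere else;
* ``ubiquitous`` — flat, well-expressed profile;
* ``host_coupled`` — per-sample mean proportional to the realized FPKM of a
  tissue-specific host gene, so circRNA and host share both specificity and
  any dysregulation;
* ``rbp_coupled`` — per-sample mean proportional to the realized FPKM of a
  tissue-specific RBP (the host gene stays non-specific); each such RBP also
  carries a tumor effect in one cancer so the same coupling exercises the
  dysregulation-attribution path;
* ``background`` — constant mean across tissues; a subset carries explicit
  per-cancer tumor effects (cancer-specific, shared-consistent and
  shared-inconsistent patterns).

A configurable global tumor-wide downscaling of circRNA means reproduces
the drop of total circRNA abundance in tumors.  All randomness flows from a
single mandatory seed; identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

import math
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CircRNARecord,
    ExpressionMatrix,
    JunctionCountMatrix,
    SampleMeta,
    TranscriptModel,
    write_expression_tsv,
    write_sample_metadata,
)

DEFAULT_TISSUES = (
    "brain",
    "esophagus",
    "lung",
    "thyroid",
    "intestine",
    "stomach",
    "liver",
)


@dataclass
class SimConfig:
    """Study conditions of a simulated cohort.

    Defaults mirror the target study design: 7 tissues, paired tumor/normal
    samples, ~20M mapped reads per library, most circRNAs lowly expressed,
    ~73.5% of host genes producing at least two circRNA isoforms, planted
    tissue-specificity at 50-fold with zero background, 4-fold tumor
    effects, and a 30% global drop of circRNA output in tumors.
    """

    rng_seed: int
    n_tissues: int = 7
    patients_per_tissue: int = 10
    n_genes: int = 300
    circ_per_gene_p: float = 0.2646  # geometric P(1 isoform); ~73.5% hosts get >= 2
    max_isoforms: int = 5
    nb_dispersion_circ: float = 0.1
    nb_dispersion_gene: float = 0.05
    baseline_circ_rpm_median: float = 0.3
    baseline_circ_rpm_sigma: float = 1.0
    baseline_gene_fpkm_median: float = 20.0
    baseline_gene_fpkm_sigma: float = 1.0
    frac_tissue_specific_circ: float = 0.10
    frac_ubiquitous_circ: float = 0.05
    frac_host_coupled: float = 0.05
    frac_rbp_coupled: float = 0.05
    frac_tissue_specific_gene: float = 0.10
    tissue_effect: float = 50.0
    de_frac_per_cancer: float = 0.02
    de_log2_effect: float = 2.0
    de_min_baseline_rpm: float = 0.5
    coupled_min_base_rpm: float = 1.0
    n_shared_consistent: int = 8
    n_shared_inconsistent: int = 4
    global_tumor_downscale: float = 0.7
    n_rbps: int = 20
    n_specific_rbps: int = 3
    circ_linear_ratio_median: float = 0.2
    circ_linear_ratio_sigma: float = 1.0
    library_size_median: float = 2.0e7
    library_size_sigma: float = 0.2
    tissues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory")
        if self.patients_per_tissue < 1:
            raise ValueError("patients_per_tissue must be >= 1")
        for name in (
            "frac_tissue_specific_circ",
            "frac_ubiquitous_circ",
            "frac_host_coupled",
            "frac_rbp_coupled",
            "frac_tissue_specific_gene",
            "de_frac_per_cancer",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.tissues:
            if self.n_tissues <= len(DEFAULT_TISSUES):
                self.tissues = DEFAULT_TISSUES[: self.n_tissues]
            else:
                extra = tuple(
                    f"tissue{i:02d}"
                    for i in range(len(DEFAULT_TISSUES), self.n_tissues)
                )
                self.tissues = DEFAULT_TISSUES + extra
        self.n_tissues = len(self.tissues)


@dataclass
class SimTruth:
    """Planted ground truth, one row per simulated feature."""

    circ: pd.DataFrame  # index circ_id: host_gene, sim_class, target_tissue, coupled_rbp, coupling_coef
    circ_de: pd.DataFrame  # circ_id, cancer, log2_effect
    gene: pd.DataFrame  # index gene_id: is_rbp, target_tissue
    gene_de: pd.DataFrame  # gene_id, cancer, log2_effect


@dataclass
class Cohort:
    junctions: JunctionCountMatrix
    gene_fpkm: ExpressionMatrix
    gene_counts: ExpressionMatrix
    samples: list[SampleMeta]
    truth: SimTruth
    transcripts: list[TranscriptModel]
    rbp_panel: list[str]
    gene_lengths_kb: dict[str, float] = field(default_factory=dict)

    @property
    def host_gene_map(self) -> dict[str, str]:
        return {r.circ_id: r.host_gene for r in self.junctions.records}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial draws parameterised by mean and dispersion alpha."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 1e-12
    if pos.any():
        n = 1.0 / alpha
        p = n / (n + mean[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


def _build_annotation(
    rng: np.random.Generator, config: SimConfig
) -> tuple[list[TranscriptModel], list[str], list[str]]:
    """Toy gene models laid head to tail on 7 chromosomes.

    Every gene has one transcript with 6-10 exons; the CDS starts inside the
    first exon and ends inside the last, leaving genuine 5'/3' UTRs so that
    genomic-origin classification sees every category.
    """
    transcripts: list[TranscriptModel] = []
    gene_ids: list[str] = []
    rbp_ids: list[str] = []
    cursors = {f"chr{i + 1}": 10_000 for i in range(7)}
    for g in range(config.n_genes):
        is_rbp = g < config.n_rbps
        gene_id = f"RBP{g + 1:03d}" if is_rbp else f"GENE{g + 1:04d}"
        if is_rbp:
            rbp_ids.append(gene_id)
        gene_ids.append(gene_id)
        chrom = f"chr{(g % 7) + 1}"
        n_exons = int(rng.integers(6, 11))
        exon_lens = rng.integers(80, 300, size=n_exons)
        intron_lens = rng.integers(500, 3000, size=n_exons - 1)
        start = cursors[chrom]
        exons = []
        pos = start
        for i in range(n_exons):
            exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        cursors[chrom] = pos + 5_000
        utr5 = int(rng.integers(20, exon_lens[0] - 10))
        utr3 = int(rng.integers(20, exon_lens[-1] - 10))
        cds = (exons[0][0] + utr5, exons[-1][1] - utr3)
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(
            TranscriptModel(f"{gene_id}.t1", gene_id, chrom, strand, tuple(exons), cds)
        )
    return transcripts, gene_ids, rbp_ids


def _build_circles(
    rng: np.random.Generator, config: SimConfig, transcripts: list[TranscriptModel]
) -> list[CircRNARecord]:
    """Back-splice records as contiguous internal exon runs of each transcript."""
    records: list[CircRNARecord] = []
    counter = 0
    for tx in transcripts:
        n_iso = min(
            int(rng.geometric(config.circ_per_gene_p)), config.max_isoforms
        )
        n_ex = len(tx.exons)
        runs = [
            (i, i + length - 1)
            for length in range(2, 6)
            for i in range(1, n_ex - 1)
            if i + length - 1 <= n_ex - 2
        ]
        chosen = rng.choice(len(runs), size=min(n_iso, len(runs)), replace=False)
        for k in sorted(chosen):
            i, j = runs[k]
            blocks = tx.exons[i : j + 1]
            counter += 1
            records.append(
                CircRNARecord(
                    tx.chrom,
                    blocks[0][0],
                    blocks[-1][1],
                    tx.strand,
                    f"hsa_circ_{counter:07d}",
                    tx.gene,
                    blocks,
                )
            )
    return records


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw one full paired cohort with planted ground truth."""
    rng = np.random.default_rng(config.rng_seed)
    tissues = list(config.tissues)
    cancers = tissues  # one cancer cohort per tissue

    # --- samples ---------------------------------------------------------
    samples: list[SampleMeta] = []
    for tissue in tissues:
        for p in range(1, config.patients_per_tissue + 1):
            patient = f"{tissue}_P{p:02d}"
            for cond, suffix in (("tumor", "T"), ("normal", "N")):
                depth = int(
                    config.library_size_median
                    * math.exp(rng.normal(0.0, config.library_size_sigma))
                )
                samples.append(
                    SampleMeta(f"{patient}{suffix}", tissue, cond, patient, depth)
                )
    n_samples = len(samples)
    lib = np.array([s.mapped_reads for s in samples], dtype=float)
    tissue_of = np.array([tissues.index(s.tissue) for s in samples])
    is_tumor = np.array([s.condition == "tumor" for s in samples])

    # --- annotation and gene expression ---------------------------------
    transcripts, gene_ids, rbp_ids = _build_annotation(rng, config)
    n_genes = len(gene_ids)
    gene_len_kb = {
        t.gene: sum(e - s for s, e in t.exons) / 1000.0 for t in transcripts
    }
    base_fpkm = config.baseline_gene_fpkm_median * np.exp(
        rng.normal(0.0, config.baseline_gene_fpkm_sigma, size=n_genes)
    )

    gene_target = np.full(n_genes, "", dtype=object)
    # force the first n_specific_rbps RBPs tissue-specific, one tissue each
    for k in range(min(config.n_specific_rbps, len(rbp_ids))):
        gene_target[k] = tissues[k % len(tissues)]
    n_ts_genes = int(round(config.frac_tissue_specific_gene * n_genes))
    non_rbp_idx = np.arange(config.n_rbps, n_genes)
    ts_pick = rng.choice(
        non_rbp_idx, size=min(n_ts_genes, len(non_rbp_idx)), replace=False
    )
    for i in ts_pick:
        gene_target[i] = tissues[int(rng.integers(len(tissues)))]

    # per-tissue mean FPKM
    gene_mean_tissue = np.tile(base_fpkm[:, None], (1, len(tissues)))
    for i in range(n_genes):
        if gene_target[i]:
            gene_mean_tissue[i, tissues.index(gene_target[i])] *= config.tissue_effect

    # per-cancer gene tumor effects
    gene_de_rows = []
    gene_effect = np.ones((n_genes, len(cancers)))
    n_de_genes = max(1, int(round(config.de_frac_per_cancer * n_genes)))
    for c, cancer in enumerate(cancers):
        pick = rng.choice(n_genes, size=n_de_genes, replace=False)
        for i in pick:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            gene_effect[i, c] = 2.0 ** (sign * config.de_log2_effect)
            gene_de_rows.append(
                {
                    "gene_id": gene_ids[i],
                    "cancer": cancer,
                    "log2_effect": sign * config.de_log2_effect,
                }
            )
    # every tissue-specific RBP is also downregulated in one cancer, so
    # RBP-coupled circRNAs exercise the dysregulation-attribution path;
    # downregulation (the RBFOX1/ESRP1 motif) keeps the coupled circRNA
    # mass from masking the global tumor-wide abundance drop
    for k in range(min(config.n_specific_rbps, len(rbp_ids))):
        cancer_idx = int(rng.integers(len(cancers)))
        if gene_effect[k, cancer_idx] == 1.0:
            gene_effect[k, cancer_idx] = 2.0 ** (-config.de_log2_effect)
            gene_de_rows.append(
                {
                    "gene_id": gene_ids[k],
                    "cancer": cancers[cancer_idx],
                    "log2_effect": -config.de_log2_effect,
                }
            )

    gene_mean_sample = gene_mean_tissue[:, tissue_of]
    tumor_cols = np.flatnonzero(is_tumor)
    gene_mean_sample[:, tumor_cols] *= gene_effect[:, tissue_of[tumor_cols]]

    len_kb = np.array([gene_len_kb[g] for g in gene_ids])
    gene_count_mean = gene_mean_sample * len_kb[:, None] * lib[None, :] / 1e6
    gene_counts = _nb_draw(rng, gene_count_mean, config.nb_dispersion_gene)
    gene_fpkm = gene_counts / (len_kb[:, None] * lib[None, :] / 1e6)

    # --- circRNAs --------------------------------------------------------
    records = _build_circles(rng, config, transcripts)
    n_circ = len(records)
    if n_circ == 0:
        raise ValueError("simulation produced no circRNAs; increase n_genes")
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    base_rpm = config.baseline_circ_rpm_median * np.exp(
        rng.normal(0.0, config.baseline_circ_rpm_sigma, size=n_circ)
    )

    sim_class = np.full(n_circ, "background", dtype=object)
    target_tissue = np.full(n_circ, "", dtype=object)
    coupled_rbp = np.full(n_circ, "", dtype=object)
    coupling_coef = np.zeros(n_circ)

    order = rng.permutation(n_circ)
    n_ts = int(round(config.frac_tissue_specific_circ * n_circ))
    n_ub = int(round(config.frac_ubiquitous_circ * n_circ))
    cursor = 0
    for i in order[cursor : cursor + n_ts]:
        sim_class[i] = "tissue_specific"
        target_tissue[i] = tissues[int(rng.integers(len(tissues)))]
    cursor += n_ts
    for i in order[cursor : cursor + n_ub]:
        sim_class[i] = "ubiquitous"
    cursor += n_ub
    # host-coupled: requires a tissue-specific host gene
    n_hc = int(round(config.frac_host_coupled * n_circ))
    hc_candidates = [
        i
        for i in order[cursor:]
        if gene_target[gene_index[records[i].host_gene]] != ""
    ]
    for i in hc_candidates[:n_hc]:
        g = gene_index[records[i].host_gene]
        sim_class[i] = "host_coupled"
        target_tissue[i] = gene_target[g]
        # coupling is identifiable only above the counting-noise floor
        base_rpm[i] = max(base_rpm[i], config.coupled_min_base_rpm)
        coupling_coef[i] = base_rpm[i] / max(base_fpkm[g], 1e-9)
    taken = set(hc_candidates[:n_hc])
    # RBP-coupled: host gene must stay non-specific
    n_rc = int(round(config.frac_rbp_coupled * n_circ))
    specific_rbp_idx = [
        k for k in range(min(config.n_specific_rbps, len(rbp_ids)))
    ]
    rc_candidates = [
        i
        for i in order[cursor:]
        if i not in taken and gene_target[gene_index[records[i].host_gene]] == ""
    ]
    for i in rc_candidates[:n_rc]:
        k = specific_rbp_idx[int(rng.integers(len(specific_rbp_idx)))]
        sim_class[i] = "rbp_coupled"
        target_tissue[i] = str(gene_target[k])
        coupled_rbp[i] = rbp_ids[k]
        base_rpm[i] = max(base_rpm[i], config.coupled_min_base_rpm)
        coupling_coef[i] = base_rpm[i] / max(base_fpkm[k], 1e-9)

    # per-sample mean RPM
    mean_rpm = np.tile(base_rpm[:, None], (1, n_samples))
    for i in range(n_circ):
        cls = sim_class[i]
        if cls == "tissue_specific":
            mask = tissue_of == tissues.index(target_tissue[i])
            mean_rpm[i, :] = 0.0
            mean_rpm[i, mask] = base_rpm[i] * config.tissue_effect
        elif cls == "ubiquitous":
            mean_rpm[i, :] = base_rpm[i] * 3.0
        elif cls == "host_coupled":
            g = gene_index[records[i].host_gene]
            mean_rpm[i, :] = coupling_coef[i] * gene_fpkm[g, :]
        elif cls == "rbp_coupled":
            k = gene_index[coupled_rbp[i]]
            mean_rpm[i, :] = coupling_coef[i] * gene_fpkm[k, :]

    # explicit tumor effects on well-expressed background circRNAs
    circ_de_rows = []
    circ_effect = np.ones((n_circ, len(cancers)))
    de_pool = [
        i
        for i in order
        if sim_class[i] == "background" and base_rpm[i] >= config.de_min_baseline_rpm
    ]
    pool_pos = 0

    def plant(i: int, cancer_idx: int, sign: float) -> None:
        circ_effect[i, cancer_idx] = 2.0 ** (sign * config.de_log2_effect)
        circ_de_rows.append(
            {
                "circ_id": records[i].circ_id,
                "cancer": cancers[cancer_idx],
                "log2_effect": sign * config.de_log2_effect,
            }
        )

    # shared patterns first: they are few and must not lose out to the
    # per-cancer specific plants when the well-expressed pool is small
    for _ in range(config.n_shared_consistent):
        if pool_pos >= len(de_pool):
            break
        i = de_pool[pool_pos]
        pool_pos += 1
        k = int(rng.integers(2, 6))
        picks = rng.choice(len(cancers), size=min(k, len(cancers)), replace=False)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for c in picks:
            plant(i, int(c), sign)
    for _ in range(config.n_shared_inconsistent):
        if pool_pos >= len(de_pool):
            break
        i = de_pool[pool_pos]
        pool_pos += 1
        k = int(rng.integers(2, 6))
        picks = rng.choice(len(cancers), size=min(k, len(cancers)), replace=False)
        signs = [1.0, -1.0] + [
            1.0 if rng.random() < 0.5 else -1.0 for _ in range(len(picks) - 2)
        ]
        for c, sign in zip(picks, signs):
            plant(i, int(c), sign)
    n_de = int(round(config.de_frac_per_cancer * n_circ))
    for c in range(len(cancers)):
        for _ in range(n_de):
            if pool_pos >= len(de_pool):
                break
            plant(de_pool[pool_pos], c, 1.0 if rng.random() < 0.5 else -1.0)
            pool_pos += 1

    mean_rpm[:, tumor_cols] *= circ_effect[:, tissue_of[tumor_cols]]
    mean_rpm[:, tumor_cols] *= config.global_tumor_downscale

    back_mean = mean_rpm * lib[None, :] / 1e6
    back = _nb_draw(rng, back_mean, config.nb_dispersion_circ)
    linear_ratio = config.circ_linear_ratio_median * np.exp(
        rng.normal(0.0, config.circ_linear_ratio_sigma, size=n_circ)
    )
    forward_mean = back_mean / linear_ratio[:, None]
    forward = _nb_draw(rng, forward_mean, config.nb_dispersion_circ)

    # --- assemble --------------------------------------------------------
    jcm = JunctionCountMatrix(records, samples, back, forward)
    sample_ids = [s.sample_id for s in samples]
    fpkm_em = ExpressionMatrix(
        gene_ids, sample_ids, gene_fpkm, "FPKM", samples=samples
    )
    counts_em = ExpressionMatrix(
        gene_ids, sample_ids, gene_counts.astype(float), "raw_count", samples=samples
    )
    truth = SimTruth(
        circ=pd.DataFrame(
            {
                "host_gene": [r.host_gene for r in records],
                "sim_class": sim_class,
                "target_tissue": target_tissue,
                "coupled_rbp": coupled_rbp,
                "coupling_coef": coupling_coef,
                "base_rpm": base_rpm,
                "linear_ratio": linear_ratio,
            },
            index=pd.Index([r.circ_id for r in records], name="circ_id"),
        ),
        circ_de=pd.DataFrame(
            circ_de_rows, columns=["circ_id", "cancer", "log2_effect"]
        ),
        gene=pd.DataFrame(
            {
                "is_rbp": [g in set(rbp_ids) for g in gene_ids],
                "target_tissue": gene_target,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        gene_de=pd.DataFrame(
            gene_de_rows, columns=["gene_id", "cancer", "log2_effect"]
        ),
    )
    return Cohort(
        jcm, fpkm_em, counts_em, samples, truth, transcripts, rbp_ids, gene_len_kb
    )


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------


def _write_gtf(transcripts: list[TranscriptModel], path: Path) -> None:
    with path.open("w") as fh:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene}"; transcript_id "{tx.tx_id}"; gene_name "{tx.gene}";'
            span = tx.span
            fh.write(
                f"{tx.chrom}\tsim\ttranscript\t{span[0] + 1}\t{span[1]}\t.\t{tx.strand}\t.\t{attrs}\n"
            )
            for s, e in tx.exons:
                fh.write(
                    f"{tx.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            for s, e in tx.cds_intervals:
                fh.write(
                    f"{tx.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{tx.strand}\t0\t{attrs}\n"
                )


def _write_calls(cohort: Cohort, calls_dir: Path) -> None:
    calls_dir.mkdir()
    jcm = cohort.junctions
    for j, sample in enumerate(jcm.samples):
        path = calls_dir / f"{sample.sample_id}.circ_calls.txt"
        with path.open("w") as fh:
            for i, rec in enumerate(jcm.records):
                n = int(jcm.back_spliced[i, j])
                if n == 0:
                    continue
                sizes = ",".join(str(e - s) for s, e in rec.exon_blocks)
                offsets = ",".join(str(s - rec.start) for s, _ in rec.exon_blocks)
                fh.write(
                    "\t".join(
                        [
                            rec.chrom,
                            str(rec.start),
                            str(rec.end),
                            f"circular_RNA/{i}",
                            "0",
                            rec.strand,
                            str(rec.start),
                            str(rec.end),
                            "0,0,0",
                            str(rec.exon_count),
                            sizes,
                            offsets,
                            str(n),
                            "circRNA",
                            rec.host_gene,
                            f"{rec.host_gene}.t1",
                            "-",
                            "-",
                        ]
                    )
                    + "\n"
                )


def _write_repeats(
    rng: np.random.Generator, transcripts: list[TranscriptModel], path: Path
) -> None:
    """Random short repeat elements dropped into a third of all introns."""
    with path.open("w") as fh:
        k = 0
        for tx in transcripts:
            for s, e in tx.introns:
                if e - s < 400 or rng.random() > 0.33:
                    continue
                start = int(rng.integers(s, e - 300))
                k += 1
                fh.write(f"{tx.chrom}\t{start}\t{start + 300}\trepeat{k}\t0\t+\n")


def write_fixture(out_dir: str | Path, cohort: Cohort, force: bool = False) -> Path:
    """Emit a complete on-disk cohort in the dialects the readers consume.

    Refuses to write into an existing non-empty directory unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise FileExistsError(f"{out} exists and is not empty")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    write_sample_metadata(cohort.samples, out / "samples.tsv")
    jcm = cohort.junctions
    sample_ids = jcm.sample_ids
    back_em = ExpressionMatrix(
        jcm.circ_ids, sample_ids, jcm.back_spliced.astype(float), "raw_count"
    )
    fwd_em = ExpressionMatrix(
        jcm.circ_ids, sample_ids, jcm.forward_spliced.astype(float), "raw_count"
    )
    write_expression_tsv(back_em, out / "circ_back_counts.tsv")
    write_expression_tsv(fwd_em, out / "circ_forward_counts.tsv")
    write_expression_tsv(cohort.gene_fpkm, out / "gene_fpkm.tsv")
    write_expression_tsv(cohort.gene_counts, out / "gene_counts.tsv")
    _write_gtf(cohort.transcripts, out / "annotation.gtf")
    _write_calls(cohort, out / "calls")
    with (out / "id_map.tsv").open("w") as fh:
        for rec in jcm.records:
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.circ_id}\n")
    with (out / "rbp_panel.tsv").open("w") as fh:
        fh.write("rbp_id\n")
        for rbp in cohort.rbp_panel:
            fh.write(f"{rbp}\n")
    rng = np.random.default_rng(0)  # repeats are fixture decoration, not truth
    _write_repeats(rng, cohort.transcripts, out / "repeats.bed")
    cohort.truth.circ.to_csv(out / "truth_circ.tsv", sep="\t")
    cohort.truth.circ_de.to_csv(out / "truth_circ_de.tsv", sep="\t", index=False)
    cohort.truth.gene.to_csv(out / "truth_gene.tsv", sep="\t")
    cohort.truth.gene_de.to_csv(out / "truth_gene_de.tsv", sep="\t", index=False)
    return out
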