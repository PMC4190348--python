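"""Synthetic study generator with recorded ground truth.

Every pipeline stage is exercised on data this module generates:
two-condition Poisson count tables with a known minority of
fold-change genes, developmental time courses containing co-expressed
modules with three temporal shapes (post-onset ramp-up, a 10-13 hpf
pulse, ramp-down) over uncorrelated background genes, promoter
sequences with PWM consensus sites planted at recorded positions,
transcript layouts with the gene partition they imply, and gene-set
annotation tables with one designed enriched term.

All generators are deterministic given a seed, and everything planted
is recorded in a :class:`SimTruth` so recovery can be checked from the
written fixtures alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .expression import ExpressionMatrix, InvalidInputError
from .motif import PWM, load_default_pwm, scan_promoter

BASES = "ACGT"

#: default stage grid: twelve points spanning 2-4-cell cleavage to 7 dpf
DEFAULT_STAGES = (
    "0.75hpf", "2.25hpf", "4.3hpf", "5.3hpf", "8hpf", "10hpf",
    "13hpf", "16hpf", "24hpf", "48hpf", "96hpf", "168hpf",
)
#: stage index after which rx3-like expression switches on (~10 hpf)
ONSET_INDEX = 5


@dataclass
class SimTruth:
    """Ground truth of one simulation.

    Only the mappings a given generator plants are populated.
    """

    de_labels: dict[str, str] | None = None          # gene -> up/down/null
    module_labels: dict[str, str] | None = None      # gene -> group1..3/background
    planted_sites: dict[str, int] | None = None      # gene -> planted site count
    planted_positions: list[tuple[str, int, str]] | None = None
    scan_hits: dict[str, int] | None = None          # gene -> reference-scan hits
    enriched_terms: list[str] | None = None
    query_genes: list[str] | None = None
    gene_clusters: list[frozenset[str]] | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.de_labels is not None:
            pd.Series(self.de_labels, name="label").to_csv(
                out / "truth_de_labels.tsv", sep="\t", index_label="gene")
        if self.module_labels is not None:
            pd.Series(self.module_labels, name="group").to_csv(
                out / "truth_module_labels.tsv", sep="\t", index_label="gene")
        if self.planted_sites is not None:
            pd.Series(self.planted_sites, name="planted").to_csv(
                out / "truth_planted_sites.tsv", sep="\t", index_label="gene")
        if self.planted_positions is not None:
            pd.DataFrame(
                self.planted_positions, columns=["gene", "offset", "strand"]
            ).to_csv(out / "truth_planted_positions.tsv", sep="\t", index=False)
        if self.scan_hits is not None:
            pd.Series(self.scan_hits, name="hits").to_csv(
                out / "truth_scan_hits.tsv", sep="\t", index_label="gene")
        if self.enriched_terms is not None or self.query_genes is not None:
            blob = {"enriched_terms": self.enriched_terms,
                    "query_genes": self.query_genes}
            (out / "truth_genesets.json").write_text(json.dumps(blob, indent=1))
        if self.gene_clusters is not None:
            with open(out / "truth_gene_clusters.tsv", "w") as fh:
                fh.write("cluster\tmembers\n")
                for i, c in enumerate(sorted(self.gene_clusters, key=sorted)):
                    fh.write(f"c{i}\t{','.join(sorted(c))}\n")

    @staticmethod
    def read(out_dir: str | Path) -> "SimTruth":
        out = Path(out_dir)
        truth = SimTruth()
        p = out / "truth_de_labels.tsv"
        if p.exists():
            truth.de_labels = pd.read_csv(p, sep="\t", index_col=0,
                                          keep_default_na=False)["label"].to_dict()
        p = out / "truth_module_labels.tsv"
        if p.exists():
            truth.module_labels = pd.read_csv(p, sep="\t", index_col=0)["group"].to_dict()
        p = out / "truth_planted_sites.tsv"
        if p.exists():
            truth.planted_sites = (
                pd.read_csv(p, sep="\t", index_col=0)["planted"].astype(int).to_dict()
            )
        p = out / "truth_planted_positions.tsv"
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            truth.planted_positions = [
                (r.gene, int(r.offset), r.strand) for r in df.itertuples()
            ]
        p = out / "truth_scan_hits.tsv"
        if p.exists():
            truth.scan_hits = (
                pd.read_csv(p, sep="\t", index_col=0)["hits"].astype(int).to_dict()
            )
        p = out / "truth_genesets.json"
        if p.exists():
            blob = json.loads(p.read_text())
            truth.enriched_terms = blob["enriched_terms"]
            truth.query_genes = blob["query_genes"]
        p = out / "truth_gene_clusters.tsv"
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            truth.gene_clusters = [
                frozenset(m.split(",")) for m in df["members"]
            ]
        return truth


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Two-condition counts
# ---------------------------------------------------------------------------

class CountsSim(NamedTuple):
    counts: ExpressionMatrix
    lengths: pd.Series
    truth: SimTruth


def make_counts(
    n_genes: int,
    n_reps: int = 3,
    lib_size: float = 1e6,
    de_fraction: float = 0.0,
    fc: float = 1.5,
    seed: int = 0,
) -> CountsSim:
    """Poisson counts for sibling/mutant pools with planted fold changes.

    Per-gene baseline abundances are log-normal (sigma = 1); exactly
    floor(n_genes * de_fraction) genes receive a condition mean ratio
    of ``fc``, split half down-in-mutant, half up (the extra gene of an
    odd count goes to down).  Condition means are split symmetrically
    in log space around the shared baseline so library sizes stay
    balanced.  ``lib_size`` is the expected reads per replicate.
    A fold change of exactly 1 plants nothing and labels every gene
    null.
    """
    if n_genes <= 0:
        raise InvalidInputError("n_genes must be positive")
    if lib_size <= 0:
        raise InvalidInputError("lib_size must be positive")
    if not 0 <= de_fraction <= 1:
        raise InvalidInputError("de_fraction must be in [0,1]")
    if fc < 1:
        raise InvalidInputError("fc must be >= 1")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base *= lib_size / base.sum()
    lengths = pd.Series(rng.integers(500, 5001, size=n_genes), index=genes,
                        name="length", dtype=int)

    labels = np.array(["null"] * n_genes, dtype=object)
    if fc > 1:
        n_de = int(math.floor(n_genes * de_fraction))
        de_idx = rng.choice(n_genes, size=n_de, replace=False)
        n_down = n_de - n_de // 2
        labels[de_idx[:n_down]] = "down"
        labels[de_idx[n_down:]] = "up"

    root = math.sqrt(fc)
    mu_sib = base.copy()
    mu_mut = base.copy()
    mu_sib[labels == "down"] *= root
    mu_mut[labels == "down"] /= root
    mu_sib[labels == "up"] /= root
    mu_mut[labels == "up"] *= root

    cols = {}
    meta_rows = []
    for cond, mu in (("sibling", mu_sib), ("mutant", mu_mut)):
        for r in range(1, n_reps + 1):
            name = f"{cond[:3]}_{r}"
            cols[name] = rng.poisson(mu)
            meta_rows.append((name, cond, str(r), "13hpf"))
    values = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "condition", "replicate", "stage"]
    ).set_index("sample")
    counts = ExpressionMatrix(values=values, units="counts", sample_meta=meta)
    truth = SimTruth(de_labels=dict(zip(genes, labels)))
    return CountsSim(counts, lengths, truth)


# ---------------------------------------------------------------------------
# Developmental time course
# ---------------------------------------------------------------------------

class TimecourseSim(NamedTuple):
    matrix: ExpressionMatrix
    truth: SimTruth


def _templates(n_stages: int) -> dict[str, np.ndarray]:
    """Unit-variance temporal templates over the stage grid.

    group1: sigmoidal ramp-up after the onset stage; group2: pulse
    peaking just after onset; group3: ramp-down mirroring group1.
    """
    i = np.arange(n_stages, dtype=float)
    onset = ONSET_INDEX * (n_stages - 1) / (len(DEFAULT_STAGES) - 1)
    up = 1.0 / (1.0 + np.exp(-(i - onset - 0.5) * 1.2))
    pulse = np.exp(-0.5 * ((i - onset - 0.5) / 1.2) ** 2)
    down = 1.0 - up
    out = {}
    for name, t in (("group1", up), ("group2", pulse), ("group3", down)):
        t = t - t.mean()
        out[name] = t / t.std(ddof=0)
    return out


def make_timecourse(
    n_genes: int,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    module_sizes: tuple[int, int, int] = (20, 20, 20),
    within_module_corr: float = 0.97,
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline_mean: float = 6.0,
) -> TimecourseSim:
    """Multi-stage expression with three planted co-expressed modules.

    Module genes share their group's temporal template scaled so the
    expected pairwise correlation equals ``within_module_corr``
    (signal amplitude s = noise_sd * sqrt(r / (1 - r))); background
    genes are independent unit-variance noise around their baselines.
    With ``noise_sd`` = 0 module profiles are identical and the
    within-module correlation is exactly 1.  Units are log2 RPKM.
    """
    if len(stages) < 6:
        raise InvalidInputError("need at least 6 stages")
    if not 0 < within_module_corr <= 1:
        raise InvalidInputError("within_module_corr must be in (0,1]")
    if sum(module_sizes) > n_genes:
        raise InvalidInputError("module sizes exceed n_genes")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    n_stages = len(stages)
    templates = _templates(n_stages)

    r = within_module_corr
    if noise_sd == 0 or r == 1:
        s, eff_noise = 1.0, 0.0
    else:
        s = noise_sd * math.sqrt(r / (1.0 - r))
        eff_noise = noise_sd

    labels = {}
    X = np.empty((n_genes, n_stages))
    baselines = baseline_mean + rng.normal(0, 1, size=n_genes)
    cursor = 0
    for name, size in zip(("group1", "group2", "group3"), module_sizes):
        for g in range(cursor, cursor + size):
            labels[genes[g]] = name
            X[g] = (baselines[g] + s * templates[name]
                    + rng.normal(0, eff_noise, size=n_stages))
        cursor += size
    for g in range(cursor, n_genes):
        labels[genes[g]] = "background"
        X[g] = baselines[g] + rng.normal(0, 1.0, size=n_stages)

    meta = pd.DataFrame(
        {"condition": "wildtype", "replicate": "1", "stage": list(stages)},
        index=pd.Index(stages, name="sample"),
    )
    m = ExpressionMatrix(
        values=pd.DataFrame(X, index=genes, columns=list(stages)),
        units="log2rpkm",
        sample_meta=meta,
    )
    return TimecourseSim(m, SimTruth(module_labels=labels))


# ---------------------------------------------------------------------------
# Promoters with planted PWM sites
# ---------------------------------------------------------------------------

class PromoterSim(NamedTuple):
    promoters: dict[str, str]
    truth: SimTruth


def _random_seq(rng: np.random.Generator, length: int, base_comp) -> str:
    codes = rng.choice(4, size=length, p=base_comp)
    return "".join(BASES[c] for c in codes)


def make_promoters(
    n_genes: int,
    length: int = 5000,
    base_comp: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    pwm: PWM | None = None,
    sites_per_gene: dict[str, int] | int = 0,
    seed: int = 0,
    reject_chance_hits: bool = False,
    scan_threshold: float = 0.8,
    max_reject_rounds: int = 200,
) -> PromoterSim:
    """Promoter FASTA with the PWM consensus planted at recorded loci.

    The background is i.i.d. under ``base_comp``; each gene receives
    its requested number of non-overlapping consensus insertions at
    recorded positions and strands (a minus-strand site inserts the
    reverse complement).  By default chance hits are left in place and
    recorded into truth by a reference scan; with
    ``reject_chance_hits`` the background is locally re-drawn until
    the scan reports exactly the planted loci, giving fixtures an
    exact truth (use for zero-hit backgrounds).
    """
    base_comp = np.asarray(base_comp, dtype=float)
    if not math.isclose(base_comp.sum(), 1.0, abs_tol=1e-9):
        raise InvalidInputError("base_comp must sum to 1")
    if (base_comp < 0).any():
        raise InvalidInputError("negative base composition")
    if pwm is None:
        pwm = load_default_pwm()
    w = pwm.width
    genes = _gene_ids(n_genes)
    if isinstance(sites_per_gene, int):
        sites = {g: sites_per_gene for g in genes}
    else:
        sites = {g: int(sites_per_gene.get(g, 0)) for g in genes}
    for g, k in sites.items():
        if k * w >= length:
            raise InvalidInputError(f"{g}: {k} sites of width {w} exceed promoter")
    rng = np.random.default_rng(seed)
    consensus = pwm.consensus
    rc = consensus.translate(str.maketrans("ACGT", "TGCA"))[::-1]

    promoters: dict[str, str] = {}
    planted_positions: list[tuple[str, int, str]] = []
    for g in genes:
        seq = list(_random_seq(rng, length, base_comp))
        placed: list[int] = []
        while len(placed) < sites[g]:
            pos = int(rng.integers(0, length - w + 1))
            if all(abs(pos - p) >= w for p in placed):
                placed.append(pos)
        placed.sort()
        strands = []
        for pos in placed:
            strand = "+" if rng.random() < 0.5 else "-"
            strands.append(strand)
            seq[pos : pos + w] = consensus if strand == "+" else rc
            planted_positions.append((g, pos, strand))
        promoters[g] = "".join(seq)
        if reject_chance_hits:
            promoters[g] = _reject_filter(
                promoters[g], placed, pwm, scan_threshold, base_comp, rng,
                max_reject_rounds, gene=g,
            )

    scan_hits = {
        g: len(scan_promoter(pwm, promoters[g], scan_threshold, gene=g))
        for g in genes
    }
    truth = SimTruth(
        planted_sites=dict(sites),
        planted_positions=planted_positions,
        scan_hits=scan_hits,
    )
    return PromoterSim(promoters, truth)


def _reject_filter(
    seq: str,
    planted: list[int],
    pwm: PWM,
    threshold: float,
    base_comp: np.ndarray,
    rng: np.random.Generator,
    max_rounds: int,
    gene: str = "",
) -> str:
    """Re-draw background bases until the scan reports only planted loci."""
    w = pwm.width
    protected = set()
    for p in planted:
        protected.update(range(p, p + w))
    chars = list(seq)
    for _ in range(max_rounds):
        hits = scan_promoter(pwm, "".join(chars), threshold)
        extras = [h for h in hits if h.offset not in planted]
        if not extras:
            return "".join(chars)
        for h in extras:
            for i in range(h.offset, h.offset + w):
                if i not in protected:
                    chars[i] = BASES[rng.choice(4, p=base_comp)]
    raise InvalidInputError(f"{gene}: could not purge chance motif hits")


# ---------------------------------------------------------------------------
# Transcript layouts
# ---------------------------------------------------------------------------

class AnnotationSim(NamedTuple):
    transcripts: list[TranscriptModel]
    expected_clusters: list[frozenset[str]]
    truth: SimTruth


def make_annotation(layout: list[tuple]) -> AnnotationSim:
    """Transcript models plus the gene partition the clustering rules imply.

    ``layout`` rows are (id, chrom, strand, exons, cds_or_None) with an
    optional sixth provenance element (default known).  The expected
    partition is computed with an independent quadratic union-find
    oracle applying the three-phase rules directly, after removing
    novel transcripts shorter than 300 bases.
    """
    transcripts = []
    for row in layout:
        tid, chrom, strand, exons, cds = row[:5]
        prov = row[5] if len(row) > 5 else "known"
        transcripts.append(
            TranscriptModel(id=tid, chrom=chrom, strand=strand,
                            exons=list(exons), cds=list(cds) if cds else None,
                            provenance=prov)
        )
    expected = brute_force_clusters(transcripts)
    return AnnotationSim(transcripts, expected, SimTruth(gene_clusters=expected))


def _merge(ivs: list) -> list:
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def _overlap_any(a: list, b: list) -> int:
    bp = 0
    for s1, e1 in _merge(a):
        for s2, e2 in _merge(b):
            bp += max(0, min(e1, e2) - max(s1, s2))
    return bp


def brute_force_clusters(
    transcripts: list[TranscriptModel], min_novel_len: int = 300
) -> list[frozenset[str]]:
    """Quadratic oracle for the three-phase gene partition."""
    ts = [t for t in transcripts
          if t.provenance == "known" or t.length >= min_novel_len]
    coding = [t for t in ts if t.has_cds]
    noncoding = [t for t in ts if not t.has_cds]
    # phase 1: all-pairs CDS overlap union-find
    parent = {t.id: t.id for t in coding}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i, a in enumerate(coding):
        for b in coding[i + 1:]:
            if (a.chrom, a.strand) == (b.chrom, b.strand) and _overlap_any(
                a.cds, b.cds
            ):
                union(a.id, b.id)
    comps: dict[str, set[str]] = {}
    for t in coding:
        comps.setdefault(find(t.id), set()).add(t.id)
    genes = [set(v) for v in comps.values()]
    # phase 2: attach by largest exon-union overlap
    remaining = []
    for t in noncoding:
        best = None
        for gi, members in enumerate(genes):
            ms = [x for x in coding if x.id in members]
            if (ms[0].chrom, ms[0].strand) != (t.chrom, t.strand):
                continue
            union_exons = [iv for m in ms for iv in m.exons]
            bp = _overlap_any(t.exons, union_exons)
            gid = min(members)
            if bp > 0 and (best is None or bp > best[0] or
                           (bp == best[0] and gid < best[2])):
                best = (bp, gi, gid)
        if best is None:
            remaining.append(t)
        else:
            genes[best[1]].add(t.id)
    # phase 3: exon-overlap components among leftovers
    parent2 = {t.id: t.id for t in remaining}

    def find2(x):
        while parent2[x] != x:
            x = parent2[x]
        return x

    for i, a in enumerate(remaining):
        for b in remaining[i + 1:]:
            if (a.chrom, a.strand) == (b.chrom, b.strand) and _overlap_any(
                a.exons, b.exons
            ):
                ra, rb = find2(a.id), find2(b.id)
                if ra != rb:
                    parent2[rb] = ra
    comps2: dict[str, set[str]] = {}
    for t in remaining:
        comps2.setdefault(find2(t.id), set()).add(t.id)
    genes.extend(set(v) for v in comps2.values())
    return sorted((frozenset(g) for g in genes), key=sorted)


# ---------------------------------------------------------------------------
# Gene-set annotation tables
# ---------------------------------------------------------------------------

class GenesetSim(NamedTuple):
    annotation: pd.DataFrame
    truth: SimTruth


def make_genesets(
    n_genes: int,
    n_terms: int = 10,
    term_size: int = 20,
    enriched_term_overlap: float = 0.8,
    seed: int = 0,
    query_size: int | None = None,
    query: list[str] | None = None,
) -> GenesetSim:
    """Annotation table with one term designed to overlap a query set.

    A query gene set (default the size of one term) is drawn — or
    supplied via ``query`` — and term ``t000`` takes
    ``enriched_term_overlap`` of its members from it, the rest from
    elsewhere, while the remaining terms are uniform random draws.
    Truth records the query and the designed term.
    """
    if term_size > n_genes:
        raise InvalidInputError("term_size exceeds n_genes")
    if not 0 <= enriched_term_overlap <= 1:
        raise InvalidInputError("overlap proportion must be in [0,1]")
    rng = np.random.default_rng(seed)
    genes = np.array(_gene_ids(n_genes))
    if query is not None:
        query = np.array(sorted(set(query) & set(genes)))
        query_size = query.size
    else:
        query_size = query_size or term_size
        query = rng.choice(genes, size=query_size, replace=False)
    n_from_query = int(round(enriched_term_overlap * term_size))
    n_from_query = min(n_from_query, query_size)
    others = np.setdiff1d(genes, query)
    rows = []
    first = list(rng.choice(query, size=n_from_query, replace=False))
    first += list(rng.choice(others, size=term_size - n_from_query, replace=False))
    for g in first:
        rows.append(("t000", "designed_term", g))
    for t in range(1, n_terms):
        for g in rng.choice(genes, size=term_size, replace=False):
            rows.append((f"t{t:03d}", f"random_term_{t}", g))
    ann = pd.DataFrame(rows, columns=["term_id", "term_name", "gene"])
    background_rate = term_size / n_genes
    enriched = ["t000"] if enriched_term_overlap > background_rate else []
    truth = SimTruth(enriched_terms=enriched, query_genes=sorted(query))
    return GenesetSim(ann, truth)


# ---------------------------------------------------------------------------
# A coherent study bundle (for the end-to-end pipeline)
# ---------------------------------------------------------------------------

def make_study(
    out_dir: str | Path,
    n_genes: int = 300,
    n_reps: int = 3,
    lib_size: float = 3e5,
    de_fraction: float = 0.2,
    fc: float = 3.0,
    promoter_length: int = 1000,
    sites_in_de: int = 3,
    seed: int = 0,
) -> dict[str, Path]:
    """Generate a coherent fixture set sharing one gene universe.

    Differentially expressed genes are placed into the three temporal
    modules, receive planted promoter motif sites, and seed the
    designed enriched term, so the full pipeline has recoverable
    structure at every stage.  Returns the written file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_counts, s_tc, s_prom, s_gs = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    )

    csim = make_counts(n_genes, n_reps=n_reps, lib_size=lib_size,
                       de_fraction=de_fraction, fc=fc, seed=s_counts)
    genes = csim.counts.gene_ids
    de_genes = sorted(g for g, lab in csim.truth.de_labels.items() if lab != "null")

    # temporal modules: DE genes split across the three groups
    third = max(1, len(de_genes) // 3)
    sizes = (third, third, len(de_genes) - 2 * third)
    tsim = make_timecourse(n_genes, module_sizes=sizes, seed=s_tc)
    # remap module labels so that module members ARE the DE genes
    order = de_genes + sorted(set(genes) - set(de_genes))
    relabel = dict(zip(_gene_ids(n_genes), order))
    tc_values = tsim.matrix.values.copy()
    tc_values.index = [relabel[g] for g in tc_values.index]
    tc_values = tc_values.loc[genes]
    tc = ExpressionMatrix(values=tc_values, units="log2rpkm",
                          sample_meta=tsim.matrix.sample_meta)
    module_labels = {relabel[g]: lab for g, lab in tsim.truth.module_labels.items()}

    psim = make_promoters(
        n_genes, length=promoter_length,
        sites_per_gene={g: (sites_in_de if g in de_genes else 0) for g in genes},
        seed=s_prom,
    )
    promoters = dict(zip(genes, psim.promoters.values()))
    gsim = make_genesets(n_genes, n_terms=8, term_size=min(40, n_genes // 5),
                         enriched_term_overlap=0.8, seed=s_gs, query=de_genes)

    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "lengths": out / "lengths.tsv",
        "timecourse": out / "timecourse.tsv",
        "stage_sheet": out / "stages.tsv",
        "promoters": out / "promoters.fa",
        "genesets": out / "genesets.tsv",
    }
    csim.counts.to_tsv(paths["counts"])
    csim.counts.sample_meta.to_csv(paths["samples"], sep="\t", index_label="sample")
    csim.lengths.to_csv(paths["lengths"], sep="\t", index_label="gene")
    tc.to_tsv(paths["timecourse"])
    tc.sample_meta.to_csv(paths["stage_sheet"], sep="\t", index_label="sample")
    from .motif import write_fasta

    write_fasta(promoters, paths["promoters"])
    gsim.annotation.to_csv(paths["genesets"], sep="\t", index=False)

    truth = SimTruth(
        de_labels=csim.truth.de_labels,
        module_labels=module_labels,
        planted_sites={g: psim.truth.planted_sites[o]
                       for g, o in zip(genes, psim.promoters)},
        scan_hits={g: psim.truth.scan_hits[o]
                   for g, o in zip(genes, psim.promoters)},
        enriched_terms=gsim.truth.enriched_terms,
        query_genes=gsim.truth.query_genes,
    )
    truth.write(out)
    return paths
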