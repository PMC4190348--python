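"""End-to-end orchestration of the analysis stages.

The pipeline composes the stages in the study's order: low-count
filtering → RPKM → Poisson DE with Bonferroni selection → (quantile
normalization, replicate averaging, log2) of the developmental time
course → co-expression network with the connectivity permutation test
and degree/fold-change correlation → temporal clustering → promoter
motif scan with permutation enrichment and the motif-count rank test
→ gene-set enrichment.  A run manifest records parameters, seeds and
per-stage row counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression as coex
from . import diffexpr, enrichment, expression, motif

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters and input paths in one validated record."""

    counts: str = ""
    sample_sheet: str = ""
    lengths: str = ""
    gtf: str = ""
    timecourse: str = ""
    stage_sheet: str = ""
    promoters: str = ""
    pwm: str = ""
    genesets: str = ""
    out_dir: str = "results"
    min_reads: int = 10
    alpha: float = 0.001
    fc: float = 1.5
    corr_threshold: float = 0.95
    mss_threshold: float = 0.8
    promoter_len: int = 5000
    n_perm: int = 1000
    k_groups: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.fc < 1:
            raise ValueError("fc must be >= 1")
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must be in (0,1]")
        if not 0 < self.mss_threshold <= 1:
            raise ValueError("mss_threshold must be in (0,1]")
        if self.min_reads < 0 or self.n_perm < 1 or self.k_groups < 1:
            raise ValueError("min_reads/n_perm/k_groups out of range")
        if self.promoter_len < 1:
            raise ValueError("promoter_len must be positive")

    @staticmethod
    def from_file(path: str) -> "PipelineConfig":
        """Flat key=value config file; '#' starts a comment."""
        kwargs = {}
        types = {f.name: type(f.default) for f in
                 PipelineConfig.__dataclass_fields__.values()}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = types[key](value)
        return PipelineConfig(**kwargs)

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                fh.write(f"{key} = {value}\n")


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dictionary.

    Stages with missing inputs are skipped and noted in the manifest.
    Any stage failure aborts with the stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(config.seed, 4)
    manifest: dict = {
        "parameters": asdict(config),
        "derived_seeds": {"connectivity": seeds[0], "motif": seeds[1]},
        "stages": {},
    }
    stage = "load"
    try:
        meta = expression.read_sample_sheet(config.sample_sheet)
        counts = expression.ExpressionMatrix.from_tsv(
            config.counts, units="counts", sample_meta=meta
        )
        counts.values = counts.values.round().astype(int)
        if config.gtf:
            from . import annotation as ann

            transcripts = ann.filter_short_novel(ann.read_gtf(config.gtf))
            genes = ann.cluster_transcripts(transcripts)
            lengths = pd.Series({g.id: g.length for g in genes})
            ann.write_genes_tsv(genes, out / "genes.tsv")
            manifest["stages"]["annotation"] = {
                "transcripts": len(transcripts), "genes": len(genes)
            }
        else:
            lengths = pd.read_csv(
                config.lengths, sep="\t", index_col=0
            ).iloc[:, 0].astype(float)

        stage = "filter"
        filtered = expression.filter_low_counts(counts, config.min_reads)
        manifest["stages"]["filter"] = {
            "genes_in": counts.values.shape[0],
            "genes_tested": filtered.values.shape[0],
        }

        stage = "diffexpr"
        de = diffexpr.run_de(
            filtered, lengths, alpha=config.alpha, fc=config.fc
        )
        diffexpr.write_de_table(de, out / "de_table.tsv")
        selected = de[de["status"] != "ns"]
        de_genes = sorted(selected["gene"])
        manifest["stages"]["diffexpr"] = {
            "selected": len(selected),
            "down_in_mutant": int((de["status"] == "down_in_mutant").sum()),
            "up_in_mutant": int((de["status"] == "up_in_mutant").sum()),
        }

        network_genes: list[str] = []
        if config.timecourse:
            stage = "timecourse"
            smeta = expression.read_sample_sheet(config.stage_sheet)
            tc = expression.ExpressionMatrix.from_tsv(
                config.timecourse, units="log2rpkm", sample_meta=smeta
            )
            if (tc.values.shape[1] > len(smeta["stage"].unique())):
                # replicate-level RPKM input: normalize, average, log2
                tc.units = "rpkm"
                tc = expression.quantile_normalize(tc)
                tc = expression.average_replicates(tc)
                tc = expression.log2_transform(tc)
            corr = coex.correlation_matrix(tc)
            background = list(set(tc.gene_ids) & set(de["gene"]))

            stage = "network"
            present = sorted(set(de_genes) & set(tc.gene_ids))
            net = coex.build_network(corr, threshold=config.corr_threshold,
                                     genes=present or None)
            coex.write_sif(net, out / "network.sif")
            coex.write_edge_table(net, out / "network_edges.tsv")
            coex.write_graphml(net, out / "network.graphml")
            network_genes = sorted(net.nodes)
            perm = coex.permutation_connectivity(
                present, sorted(background), corr,
                n_perm=config.n_perm, seed=seeds[0],
            ) if len(present) >= 2 else None
            if perm is not None:
                perm.to_frame().to_csv(out / "connectivity.tsv", sep="\t",
                                       index=False, float_format="%.6g")
            fc_abs = de.set_index("gene")["log2fc"].abs()
            if network_genes:
                try:
                    r, slope, intercept = coex.degree_fc_correlation(net, fc_abs)
                    deg_fc = {"r": r, "slope": slope, "intercept": intercept}
                except coex.UndefinedVarianceError:
                    deg_fc = {"error": "zero variance"}
            else:
                deg_fc = {"error": "empty network"}
            manifest["stages"]["network"] = {
                "nodes": net.number_of_nodes(),
                "edges": net.number_of_edges(),
                "connectivity": None if perm is None else perm.observed,
                "connectivity_p": None if perm is None else perm.p,
                "degree_fc": deg_fc,
            }

            stage = "clustering"
            z = expression.zscore_rows(
                expression.ExpressionMatrix(
                    values=tc.values.loc[present], units=tc.units,
                    sample_meta=tc.sample_meta,
                )
            ) if present else None
            if z is not None and z.values.shape[0] >= config.k_groups:
                groups = coex.hierarchical_cluster(z, k=config.k_groups)
                groups.to_csv(out / "temporal_groups.tsv", sep="\t",
                              index_label="gene")
                manifest["stages"]["clustering"] = {
                    "genes": int(groups.size),
                    "groups": int(groups.nunique()),
                }

        if config.promoters:
            stage = "motif"
            promoters = motif.read_fasta(config.promoters)
            pwm = (motif.read_transfac(config.pwm) if config.pwm
                   else motif.load_default_pwm())
            hits = motif.scan_promoters(pwm, promoters, config.mss_threshold)
            flat = [h for hs in hits.values() for h in hs]
            motif.write_hits_bed(flat, out / "motif_hits.tsv", pwm.width)
            hit_counts = {g: len(hs) for g, hs in hits.items()}
            query = [g for g in de_genes if g in promoters]
            if query:
                p_genes, p_freq = motif.permutation_motif_enrichment(
                    query, promoters, pwm, threshold=config.mss_threshold,
                    n_perm=config.n_perm, seed=seeds[1],
                    hit_counts=hit_counts,
                )
                fc_abs = de.set_index("gene")["log2fc"].abs()
                wil = motif.wilcoxon_by_motif_count(
                    fc_abs, pd.Series(hit_counts),
                    bins=[(0, 0), (1, 2), (3, 10**9)],
                )
                wil.to_csv(out / "motif_rank_test.tsv", sep="\t", index=False)
                manifest["stages"]["motif"] = {
                    "genes_scanned": len(promoters),
                    "query_with_hits": int(p_genes.observed),
                    "query_size": len(query),
                    "p_gene_proportion": p_genes.p,
                    "p_motif_frequency": p_freq.p,
                }

        if config.genesets:
            stage = "enrichment"
            terms, names = enrichment.read_annotation(config.genesets)
            universe = set(filtered.gene_ids)
            query = set(de_genes) & universe
            if query:
                table = enrichment.fisher_enrichment(
                    query, terms, universe, term_names=names
                )
                enrichment.write_enrichment(table, out / "enrichment.tsv")
                manifest["stages"]["enrichment"] = {
                    "terms_tested": len(table),
                    "terms_q_lt_0.05": int((table["q"] < 0.05).sum()),
                }
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
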