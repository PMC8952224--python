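"""End-to-end orchestration: diffexpr -> lncRNA discovery -> target
prediction -> ceRNA network -> PPI hubs -> key axes -> enrichment.

All numeric thresholds live in :class:`PipelineConfig` with the study's
published values as defaults and are echoed into the run manifest, together
with per-stage audit counts and a SHA-256 digest of every output file.
Stages communicate only through files in the run directory; re-running with
the same inputs and config reproduces the directory bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io_formats as iof
from .cerna_network import build_cerna, network_summary
from .diffexpr import TierThresholds, association, classify, test_de
from .enrichment import enrich, results_frame
from .graph_hubs import (
    DEFAULT_MIN_SCORE,
    DEFAULT_R_THRESHOLD,
    DEFAULT_TOP_K,
    filter_ppi,
    intersect_with_cerna,
    mcc_scores,
    rank_axes,
    top_hubs,
)
from .lncrna_discovery import FilterConfig, filter_candidates
from .synthetic_data import StudyData, read_study
from .target_prediction import (
    DEFAULT_MIN_PAIR,
    DEFAULT_NDG_THRESHOLD,
    DEFAULT_WINDOW_BP,
    cis_targets,
    merge_targets,
    trans_targets,
)

__all__ = ["PipelineConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass(frozen=True)
class PipelineConfig:
    study_dir: str
    out_dir: str
    thresholds: TierThresholds = TierThresholds()
    filter_config: FilterConfig = FilterConfig()
    cis_window_bp: int = DEFAULT_WINDOW_BP
    ndg_threshold: float = DEFAULT_NDG_THRESHOLD
    min_pair: int = DEFAULT_MIN_PAIR
    ppi_min_score: float = DEFAULT_MIN_SCORE
    hub_k: int = DEFAULT_TOP_K
    r_threshold: float = DEFAULT_R_THRESHOLD
    source_rule: str = "any"
    restrict_targets_to_de: bool = True
    seed: int = 0

    def validate(self) -> None:
        self.thresholds.validate()
        if self.cis_window_bp <= 0:
            raise ValueError("cis_window_bp must be positive")
        if self.min_pair < 2:
            raise ValueError("min_pair must be >= 2")
        if not 0 <= self.ppi_min_score <= 1:
            raise ValueError("ppi_min_score must lie in [0, 1]")
        if self.hub_k <= 0:
            raise ValueError("hub_k must be positive")
        if not -1 <= self.r_threshold <= 1:
            raise ValueError("r_threshold must lie in [-1, 1]")
        if self.source_rule not in ("any", "all"):
            raise ValueError(f"unknown source_rule {self.source_rule!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> Path:
    """Run every stage on the study in ``config.study_dir``.

    Returns the run directory. Raises :class:`PipelineError` naming the
    failing stage on any error.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit: dict[str, dict] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err
        return wrap

    study: StudyData = stage("load")(lambda: read_study(config.study_dir))
    control, treated = study.config.control_label, study.config.treated_label

    # --- differential expression ------------------------------------------
    def _diffexpr():
        de = test_de(study.counts, control, treated)
        cls = classify(de, study.fpkm, control, treated, config.thresholds)
        cls.to_csv(out / "de.tsv", sep="\t")
        assoc = {}
        for tier, groups in (
            ("screening", {"mRNA": ["mRNA"], "ncRNA": ["lncRNA", "miRNA"]}),
            ("stringent", None),
        ):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    a = association(cls, tier, groups)
                assoc[tier] = {
                    "counts": a.table[["down", "up"]].to_dict("index"),
                    "chi_square": a.chi_square,
                    "dof": a.dof,
                    "p_value": a.p_value,
                    "fisher_p": a.fisher_p,
                }
            except ValueError:
                assoc[tier] = None
        (out / "association.json").write_text(
            json.dumps(assoc, sort_keys=True, indent=1)
        )
        return cls

    classified = stage("diffexpr")(_diffexpr)
    audit["diffexpr"] = {
        "genes_tested": int(len(classified)),
        "screening": int(classified["screening"].sum()),
        "stringent": int(classified["stringent"].sum()),
        "cerna_lnc": int(classified["cerna_lnc"].sum()),
        "cerna_small": int(classified["cerna_small"].sum()),
    }

    # --- lncRNA discovery --------------------------------------------------
    def _discovery():
        cands = [t for t in study.transcripts if t.biotype == "lncRNA_candidate"]
        reference = [
            t
            for t in study.transcripts
            if t.biotype in ("protein_coding", "known_lncRNA")
        ]
        survivors, traces, reports = filter_candidates(
            cands, study.fpkm, reference, config.filter_config
        )
        pd.DataFrame(
            [
                {
                    "transcript_id": t.transcript_id,
                    "step_failed": 0 if t.step_failed is None else t.step_failed,
                    "reason": t.reason,
                }
                for t in traces
            ]
        ).to_csv(out / "lnc_filter_trace.tsv", sep="\t", index=False)
        reports.to_csv(out / "coding_potential.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"transcript_id": [t.transcript_id for t in survivors]}
        ).to_csv(out / "lnc_candidates.tsv", sep="\t", index=False)
        return survivors

    survivors = stage("lncrna_discovery")(_discovery)
    known_lnc_ids = {
        t.transcript_id for t in study.transcripts if t.biotype == "known_lncRNA"
    }
    lnc_whitelist = {t.transcript_id for t in survivors} | known_lnc_ids
    audit["lncrna_discovery"] = {
        "candidates_in": sum(
            1 for t in study.transcripts if t.biotype == "lncRNA_candidate"
        ),
        "survivors": len(survivors),
        "known_lncRNAs": len(known_lnc_ids),
    }

    # --- target prediction -------------------------------------------------
    def _targets():
        de_lnc = set(
            classified.index[classified["cerna_lnc"]]
        ) & lnc_whitelist
        de_mrna = set(
            classified.index[
                classified["stringent"] & (classified["gene_class"] == "mRNA")
            ]
        )
        lnc_models = [t for t in study.transcripts if t.transcript_id in de_lnc]
        coding_models = [
            t for t in study.transcripts if t.biotype == "protein_coding"
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cis = cis_targets(lnc_models, coding_models, config.cis_window_bp)
            if config.restrict_targets_to_de:
                cis = [p for p in cis if p.gene_id in de_mrna]
            lnc_seqs = {t.transcript_id: t.sequence for t in lnc_models}
            m_seqs = {
                g: study.sequences[g] for g in sorted(de_mrna) if g in study.sequences
            }
            trans = trans_targets(
                lnc_seqs, m_seqs, config.ndg_threshold, config.min_pair
            )
        merged = merge_targets(cis, trans)
        merged.to_csv(out / "targets.tsv", sep="\t", index=False)
        return merged

    targets = stage("target_prediction")(_targets)
    audit["target_prediction"] = {
        "pairs": int(len(targets)),
        "cis": int((targets["evidence"] == "cis").sum()),
        "trans": int((targets["evidence"] == "trans").sum()),
        "both": int((targets["evidence"] == "both").sum()),
    }

    # --- ceRNA network -----------------------------------------------------
    def _cerna():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = build_cerna(
                classified,
                study.mi_mrna,
                study.mi_lnc,
                config.source_rule,
                lnc_whitelist,
            )
        iof.write_network(net, out / "cerna_network.tsv", dialect="tsv")
        (out / "cerna_summary.json").write_text(
            json.dumps(network_summary(net), sort_keys=True, indent=1)
        )
        return net

    network = stage("cerna_network")(_cerna)
    audit["cerna_network"] = network_summary(network)["total"]

    # --- PPI hubs and key axes --------------------------------------------
    def _hubs():
        cerna_mrnas = network.nodes("mRNA")
        edges = study.ppi.edges
        sub = edges[
            edges["protein_a"].isin(cerna_mrnas)
            & edges["protein_b"].isin(cerna_mrnas)
        ].reset_index(drop=True)
        graph = filter_ppi(iof.PPITable(sub), config.ppi_min_score)
        scores = mcc_scores(graph)
        pd.DataFrame(
            [{"node_id": s.node_id, "mcc": s.mcc, "rank": s.rank} for s in scores]
        ).to_csv(out / "hub_scores.tsv", sep="\t", index=False)
        hubs = top_hubs(scores, config.hub_k) if scores else set()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            key_net = intersect_with_cerna(network, hubs)
            axes = rank_axes(
                key_net,
                study.fpkm,
                {s.node_id: s.mcc for s in scores},
                config.r_threshold,
            )
        pd.DataFrame(
            [
                {
                    "lncRNA_id": a.lncRNA_id,
                    "miRNA_id": a.miRNA_id,
                    "mRNA_id": a.mRNA_id,
                    "mcc_of_mRNA": a.mcc_of_mRNA,
                    "pearson_r": a.pearson_r,
                }
                for a in axes
            ]
        ).to_csv(out / "key_axes.tsv", sep="\t", index=False)
        return hubs, axes

    hubs, axes = stage("graph_hubs")(_hubs)
    audit["graph_hubs"] = {"hub_genes": len(hubs), "key_axes": len(axes)}

    # --- enrichment --------------------------------------------------------
    def _enrich():
        query = sorted(
            classified.index[
                classified["stringent"] & (classified["gene_class"] == "mRNA")
            ]
        )
        universe = sorted(
            classified.index[classified["gene_class"] == "mRNA"]
        )
        if not query:
            results = []
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results = enrich(query, study.gene_sets, universe)
        results_frame(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        return results

    results = stage("enrichment")(_enrich)
    audit["enrichment"] = {
        "sets_tested": len(results),
        "significant_fdr_0.05": sum(1 for r in results if r.fdr <= 0.05),
    }

    # --- manifest ----------------------------------------------------------
    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "study_seed": study.config.seed,
        "audit": audit,
        "file_sha256": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1)
    )
    return out
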