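"""End-to-end orchestration: simulate -> index -> screen -> 4DTv -> signatures
-> enrichment, with seeded determinism and a machine-readable report.

The report is one row per gene joining every line of evidence, written as a
TSV with a JSON metadata sidecar (configuration hash, seed, versions,
summary counts).  Identical configuration and seed give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .enrichment import build_table, fisher_exact
from .fourdtv import ci_membership_test, fourdtv, one_to_one_pairs
from .hgt_index import DEFAULT_THRESHOLD, Verdict, call_genes
from .screen import ScreenVerdict, screen_genes
from .signatures import classify_membership, find_diagnostic_blocks
from .simulate import SimulatedDataset, SimulationConfig, simulate_dataset

ALL_STAGES = ("hgt_index", "screen", "fourdtv", "signatures", "enrich")


@dataclass
class PipelineParams:
    """Tunable thresholds of the downstream stages."""

    threshold: float = DEFAULT_THRESHOLD
    exclusion: tuple[str, ...] = ()
    identity_ceiling: float = 80.0
    identity_min_aln: int = 100
    depth_lo: float = 0.5
    depth_hi: float = 2.0
    synteny_window: int = 5
    synteny_min_anchors: int = 2
    required_supporting: int = 1
    ci_alpha: float = 0.05
    signature_focal_clade: str = "bilateria"
    signature_p_in: float = 0.9
    signature_p_out: float = 0.1
    signature_min_width: int = 2
    signature_match_fraction: float = 0.8


@dataclass
class RunReport:
    per_gene: pd.DataFrame
    metadata: dict

    def write(self, outdir: str | Path) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tsv = outdir / "report.tsv"
        meta = outdir / "report.json"
        self.per_gene.to_csv(tsv, sep="\t", index=False, float_format="%.6g")
        with open(meta, "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return tsv, meta


def _config_hash(config: SimulationConfig, params: PipelineParams) -> str:
    blob = json.dumps(
        {"simulation": dataclasses.asdict(config), "params": dataclasses.asdict(params)},
        sort_keys=True,
    ).encode()
    return hashlib.sha256(blob).hexdigest()


def run_all(
    config: SimulationConfig,
    params: PipelineParams | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
    dataset: SimulatedDataset | None = None,
) -> RunReport:
    """Run the full inference on a (simulated) dataset.

    Stages not named in ``stages`` are skipped and their report columns left
    absent.  The enrichment universe is every gene not screened out as a
    suspect contaminant (the annotation's credible gene set).
    """
    if params is None:
        params = PipelineParams()
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    if dataset is None:
        dataset = simulate_dataset(config)
    genome = dataset.genome
    gene_ids = sorted(dataset.truth.origins)
    report = pd.DataFrame({"gene_id": gene_ids})
    summary: dict = {"n_genes": len(gene_ids)}

    calls_by_gene: dict[str, Verdict] = {}
    if "hgt_index" in stages:
        calls = call_genes(
            dataset.protein_hits,
            dataset.query_lengths,
            exclusion=frozenset(params.exclusion),
            threshold=params.threshold,
        )
        calls_by_gene = {c.gene_id: c.verdict for c in calls}
        cdf = pd.DataFrame(
            {
                "gene_id": [c.gene_id for c in calls],
                "h_index": [c.h_index for c in calls],
                "best_nonmetazoan": [
                    c.best_nonmetazoan[0] if c.best_nonmetazoan else "" for c in calls
                ],
                "best_metazoan": [
                    c.best_metazoan[0] if c.best_metazoan else "" for c in calls
                ],
                "hgt_verdict": [c.verdict.value for c in calls],
            }
        )
        report = report.merge(cdf, on="gene_id", how="left")
        summary["n_putative_hgt"] = int(
            (report["hgt_verdict"] == Verdict.PUTATIVE_HGT.value).sum()
        )

    screen_by_gene: dict[str, ScreenVerdict] = {}
    if "screen" in stages:
        syn_rbh = one_to_one_pairs(genome.synteny_hits_ab, genome.synteny_hits_ba)
        evidence = screen_genes(
            genome.genes,
            genome.nt_hits,
            genome.depths,
            focal_order=genome.focal_order,
            reference_order=genome.reference_order,
            rbh_pairs=syn_rbh,
            min_aln=params.identity_min_aln,
            ceiling=params.identity_ceiling,
            depth_lo=params.depth_lo,
            depth_hi=params.depth_hi,
            window=params.synteny_window,
            min_anchors=params.synteny_min_anchors,
            required_supporting=params.required_supporting,
        )
        screen_by_gene = {e.gene_id: e.verdict for e in evidence}
        sdf = pd.DataFrame(
            {
                "gene_id": [e.gene_id for e in evidence],
                "multi_exon": [e.multi_exon for e in evidence],
                "identity_ok": [e.identity_ok for e in evidence],
                "max_nonmetazoan_identity": [
                    e.max_nonmetazoan_identity for e in evidence
                ],
                "depth_ok": [e.depth_ok for e in evidence],
                "depth_ratio": [e.depth_ratio for e in evidence],
                "synteny_ok": [e.synteny_ok for e in evidence],
                "n_synteny_anchors": [e.n_synteny_anchors for e in evidence],
                "screen_verdict": [e.verdict.value for e in evidence],
            }
        )
        report = report.merge(sdf, on="gene_id", how="left")
        summary["n_suspect_contaminant"] = int(
            (report["screen_verdict"] == ScreenVerdict.SUSPECT_CONTAMINANT.value).sum()
        )

    if "fourdtv" in stages:
        rbh = one_to_one_pairs(genome.ortho_hits_ab, genome.ortho_hits_ba)
        paired = [g for g, _ in rbh if g in genome.ortho_pairs]
        results = {g: fourdtv(genome.ortho_pairs[g]) for g in paired}
        background = list(results.values())
        verdicts = ci_membership_test(
            [results[g] for g in paired], background, alpha=params.ci_alpha
        )
        fdf = pd.DataFrame(
            {
                "gene_id": paired,
                "fourdtv_value": [results[g].value for g in paired],
                "fourdtv_n_sites": [results[g].n_sites for g in paired],
                "fourdtv_verdict": verdicts,
            }
        )
        report = report.merge(fdf, on="gene_id", how="left")
        summary["n_orthologue_pairs"] = len(paired)

    if "signatures" in stages:
        aln = genome.clade_alignment
        blocks = find_diagnostic_blocks(
            aln,
            params.signature_focal_clade,
            p_in=params.signature_p_in,
            p_out=params.signature_p_out,
            min_width=params.signature_min_width,
        )
        rows = []
        for row_id, gid in sorted(genome.candidate_rows.items()):
            verdict = classify_membership(
                aln.row(row_id),
                blocks,
                aln.n_columns,
                match_fraction=params.signature_match_fraction,
            )
            rows.append({"gene_id": gid, "signature_verdict": verdict.value})
        if rows:
            report = report.merge(pd.DataFrame(rows), on="gene_id", how="left")
        else:
            report["signature_verdict"] = pd.NA
        summary["n_signature_blocks"] = len(blocks)

    # final call combining index and screen
    if "hgt_index" in stages and "screen" in stages:
        def _final(row) -> str:
            if row["screen_verdict"] == ScreenVerdict.SUSPECT_CONTAMINANT.value:
                return "contaminant"
            if row["hgt_verdict"] == Verdict.PUTATIVE_HGT.value:
                return "hgt"
            return "native"

        report["final_call"] = report.apply(_final, axis=1)
        summary["n_final_hgt"] = int((report["final_call"] == "hgt").sum())
        summary["n_final_contaminant"] = int(
            (report["final_call"] == "contaminant").sum()
        )

    if "enrich" in stages:
        if "final_call" not in report.columns:
            raise ValueError("enrich stage requires hgt_index and screen stages")
        universe = report.loc[report["final_call"] != "contaminant", "gene_id"]
        hgt_flags = {
            g: v == "hgt"
            for g, v in zip(report["gene_id"], report["final_call"])
            if g in set(universe)
        }
        table = build_table(hgt_flags, genome.de_flags, universe=universe)
        odds, p = fisher_exact(table)
        summary["enrichment"] = {
            "table": [table.a, table.b, table.c, table.d],
            "odds_ratio": odds if odds == odds and odds != float("inf") else str(odds),
            "p_value": p,
        }

    metadata = {
        "package": "hgtscreen",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config, params),
        "simulation": dataclasses.asdict(config),
        "params": dataclasses.asdict(params),
        "stages": list(stages),
        "summary": summary,
    }
    return RunReport(per_gene=report, metadata=metadata)


def evaluate_against_truth(report: RunReport, truth) -> dict[str, dict[str, float]]:
    """Precision and recall of the planted-origin recovery, per class.

    Uses the report's ``final_call`` column for the hgt and contaminant
    classes.  A vacuously empty prediction or truth set scores 1.0.
    """
    df = report.per_gene
    if "final_call" not in df.columns:
        raise ValueError("report lacks final_call (run hgt_index and screen stages)")
    out: dict[str, dict[str, float]] = {}
    for cls in ("hgt", "contaminant"):
        pred = set(df.loc[df["final_call"] == cls, "gene_id"])
        true = {g for g, o in truth.origins.items() if o == cls}
        tp = len(pred & true)
        precision = tp / len(pred) if pred else 1.0
        recall = tp / len(true) if true else 1.0
        out[cls] = {
            "precision": precision,
            "recall": recall,
            "n_predicted": len(pred),
            "n_true": len(true),
        }
    return out
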