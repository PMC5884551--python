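"""End-to-end orchestration: simulation -> orthology -> scan -> expression
-> enrichment -> report.

Every stage writes its tables into the run directory and contributes to a
machine-readable summary; all randomness derives from the config seed via
named substreams, so identical configs give byte-identical summaries.
"""

from __future__ import annotations

import sys
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from psgscan import __version__, io
from psgscan.enrichment import AnnotationMap, fc_set_test, hypergeom_enrich, overlap_test
from psgscan.errors import PsgscanError
from psgscan.expression import (
    classify_quadrants,
    de_test,
    directionality_test,
    quadrant_fisher,
)
from psgscan.io import RunConfig
from psgscan.orthology import assign_orthologs, select_isoforms
from psgscan.screening import bias_check, scan_branch, union_psgs
from psgscan.selection import BranchSiteParams
from psgscan.simulate import (
    CountSimSpec,
    simulate_cds_catalog,
    simulate_codon_alignment,
    simulate_counts,
    simulate_tree,
)

STAGES = ("simulate", "orthologs", "scan", "expression", "enrich", "report")


def stage_seed(seed: int, stage: str) -> int:
    """Named per-stage substream seed derived from the config seed."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.write(outdir / "config.txt")
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "candidate_q": config.candidate_q,
            "de_q": config.de_q,
            "site_posterior": config.site_posterior,
        },
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        _log(stage, "starting")
        try:
            _RUNNERS[stage](config, outdir, state, summary)
        except PsgscanError:
            _log(stage, "failed; partial outputs preserved")
            raise
        _log(stage, "done")
    io.write_summary(outdir / "summary.json", summary)
    return summary


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config, outdir, state, summary):
    rng = np.random.default_rng(stage_seed(config.seed, "simulate"))
    tree = simulate_tree(config.n_taxa, config.tree_depth, seed=stage_seed(config.seed, "tree"))
    io.write_newick(outdir / "tree.nwk", tree)

    genes = [f"g{i + 1:05d}" for i in range(config.n_expression_genes)]
    scan_genes = genes[: config.n_scan_genes]
    n_selected = int(round(config.selected_fraction * len(scan_genes)))
    selected = set(scan_genes[:n_selected])  # ids are arbitrary; a prefix is fine

    alignments = {}
    truth_rows = []
    for gene in scan_genes:
        sel = gene in selected
        params = BranchSiteParams(
            kappa=config.kappa,
            omega0=config.omega0,
            omega2=config.omega2 if sel else 1.0,
            p0=config.p0,
            p1=config.p1,
        )
        aln, _ = simulate_codon_alignment(
            tree, params, config.n_codons,
            foreground=config.foregrounds[0],
            seed=int(rng.integers(2**31)),
        )
        alignments[gene] = aln
        io.write_alignment_fasta(outdir / f"aln_{gene}.fasta", aln)
        truth_rows.append({"gene": gene, "selected": sel})
    pd.DataFrame(truth_rows).to_csv(outdir / "scan_truth.tsv", sep="\t", index=False)

    count_spec = CountSimSpec(
        n_genes=config.n_expression_genes,
        dispersion=config.dispersion,
        regulated_fraction=config.regulated_fraction,
        q1_prob=config.q1_prob,
        psg_indices=tuple(genes.index(g) for g in sorted(selected)),
        seed=stage_seed(config.seed, "counts"),
    )
    counts_a, counts_b, count_truth = simulate_counts(count_spec)
    io.write_counts(outdir / "counts_a.tsv", outdir / "samples_a.tsv", counts_a)
    io.write_counts(outdir / "counts_b.tsv", outdir / "samples_b.tsv", counts_b)

    catalogs, catalog_truth = simulate_cds_catalog(
        n_genes=20, n_species=min(config.n_taxa, 4), isoforms_per_gene=2,
        divergence=0.05, seed=stage_seed(config.seed, "catalog"),
    )
    for sp, recs in catalogs.items():
        io.write_fasta_catalog(outdir / f"catalog_{sp}.fasta", recs)

    annotation = _simulate_annotation(config, genes, selected)
    with open(outdir / "annotation.tsv", "w") as fh:
        for gene, term in annotation:
            fh.write(f"{gene}\t{term}\n")

    state.update(
        tree=tree, alignments=alignments, selected_truth=selected,
        counts_a=counts_a, counts_b=counts_b, count_truth=count_truth,
        catalogs=catalogs, catalog_truth=catalog_truth, genes=genes,
        annotation=annotation,
    )
    summary["simulate"] = {
        "n_scan_genes": len(scan_genes),
        "n_true_selected": len(selected),
        "n_expression_genes": len(genes),
        "n_catalog_genes": 20,
    }


def _simulate_annotation(config, genes, selected):
    """Random gene-term table plus one term concentrated on the planted PSGs."""
    rng = np.random.default_rng(stage_seed(config.seed, "annotation"))
    pairs = []
    terms = [f"T{k + 1:03d}" for k in range(config.n_terms)]
    for gene in genes:
        for term in terms:
            if rng.random() < 0.02:
                pairs.append((gene, term))
    for gene in sorted(selected):
        pairs.append((gene, "T_longevity"))
    extra = rng.choice(len(genes), size=max(2 * len(selected), 10), replace=False)
    for i in sorted(extra):
        pairs.append((genes[i], "T_longevity"))
    return sorted(set(pairs))


def _stage_orthologs(config, outdir, state, summary):
    catalogs = state["catalogs"]
    truth = state["catalog_truth"]
    anchor = sorted(catalogs)[0]
    groups = [select_isoforms(g) for g in assign_orthologs(catalogs, anchor)]
    manifest = []
    recovered = 0
    for g in groups:
        manifest.append(
            {
                "group": g.group_id,
                "anchor_gene": g.anchor_gene,
                "n_species": len(g.chosen),
                "members": ";".join(
                    f"{sp}:{r.gene}:{r.isoform}" for sp, r in sorted(g.chosen.items())
                ),
            }
        )
        for sp, rec in g.chosen.items():
            if sp == anchor:
                continue
            key = tuple(sorted([(anchor, g.anchor_gene), (sp, rec.gene)]))
            pair = (key[0][0], key[0][1], key[1][0], key[1][1])
            recovered += pair in truth.ortholog_pairs
    expected = len(groups) * (len(catalogs) - 1)
    pd.DataFrame(manifest).to_csv(outdir / "ortholog_groups.tsv", sep="\t", index=False)
    summary["orthologs"] = {
        "anchor": anchor,
        "n_groups": len(groups),
        "recovered_pairs": recovered,
        "expected_pairs": expected,
        "recovery": recovered / expected if expected else float("nan"),
    }
    state["groups"] = groups


def _stage_scan(config, outdir, state, summary):
    tree = state["tree"]
    alignments = state["alignments"]
    scans = []
    for k, fg in enumerate(config.foregrounds):
        scan = scan_branch(
            alignments, tree, fg,
            q_threshold=config.candidate_q,
            n_starts=config.n_starts,
            seed=stage_seed(config.seed, f"scan_{k}"),
            posterior_threshold=config.site_posterior,
        )
        rows = [
            {
                "gene": r.gene, "branch": r.branch,
                "lnl_null": round(r.lnl_null, 6), "lnl_alt": round(r.lnl_alt, 6),
                "stat": round(r.statistic, 6), "p": r.p, "q": r.q,
                "approved": r.approved,
                "selected_sites": ",".join(f"{pos}:{post:.3f}" for pos, post in r.selected_sites),
            }
            for r in scan.records
        ]
        pd.DataFrame(rows).to_csv(
            outdir / f"scan_branch{k + 1}.tsv", sep="\t", index=False
        )
        scans.append(scan)
    union, multi = union_psgs(scans)
    pd.DataFrame(
        [{"gene": g, "branches": ";".join(bs)} for g, bs in multi]
    ).to_csv(outdir / "multi_branch_psgs.tsv", sep="\t", index=False)
    tested = set(alignments)
    if len(union) >= 2 and len(tested - union) >= 2:
        report = bias_check(union, tested, alignments)
        pd.DataFrame(
            [{"feature": k, **v} for k, v in report.features.items()]
        ).to_csv(outdir / "bias_checks.tsv", sep="\t", index=False)
    truth = state["selected_truth"]
    summary["scan"] = {
        "branches": [s.branch for s in scans],
        "tested": sum(len(s.records) for s in scans),
        "candidates": sum(len(s.candidates) for s in scans),
        "psgs_union": len(union),
        "true_positives": len(union & truth),
        "multi_branch_genes": len(multi),
    }
    state["psgs"] = union


def _stage_expression(config, outdir, state, summary):
    de_a = de_test(state["counts_a"], q_threshold=config.de_q)
    de_b = de_test(state["counts_b"], q_threshold=config.de_q)
    for name, de in (("de_a", de_a), ("de_b", de_b)):
        pd.DataFrame(
            [
                {"gene": r.gene, "lfc": round(r.lfc, 6), "p": r.p, "q": r.q,
                 "regulated": r.regulated}
                for r in de
            ]
        ).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    psgs = state.get("psgs", state["selected_truth"])
    table = classify_quadrants(de_a, de_b, psgs)
    rows = [
        {"quadrant": q, "psg": table.counts[q]["psg"], "other": table.counts[q]["other"]}
        for q in ("I", "II", "III", "IV")
    ]
    pd.DataFrame(rows).to_csv(outdir / "quadrants.tsv", sep="\t", index=False)
    direction = directionality_test(de_a, de_b, psgs)
    summary["expression"] = {
        "regulated_a": sum(r.regulated for r in de_a),
        "regulated_b": sum(r.regulated for r in de_b),
        "quadrant_counts": {q: table.counts[q] for q in table.counts},
        "quadrant_I_psgs": table.counts["I"]["psg"],
        "quadrant_fisher_p": quadrant_fisher(table),
        "directionality": direction,
    }
    state["de_a"], state["de_b"], state["quadrants"] = de_a, de_b, table


def _stage_enrich(config, outdir, state, summary):
    genes = state["genes"]
    ann = AnnotationMap.from_pairs(state["annotation"], universe=genes)
    psgs = set(state.get("psgs", state["selected_truth"])) & set(genes)
    records = hypergeom_enrich(psgs, ann)
    pd.DataFrame(
        [
            {"term": r.term, "overlap": r.overlap, "term_size": r.term_size,
             "p": r.p, "q": r.q}
            for r in records
        ]
    ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    significant = [r.term for r in records if r.q < 0.1]
    # fold-change-based term perturbation in the long-lived species
    lfc = {r.gene: r.lfc for r in state.get("de_a", []) if r.regulated}
    if lfc:
        fc_records = fc_set_test(lfc, ann)
        pd.DataFrame(
            [
                {"term": r.term, "direction": r.direction, "members": r.overlap,
                 "p": r.p, "q": r.q}
                for r in fc_records
            ]
        ).to_csv(outdir / "fc_perturbation.tsv", sep="\t", index=False)
    longevity_genes = ann.term_genes.get("T_longevity", set())
    p_overlap = (
        overlap_test(psgs, longevity_genes, set(genes)) if longevity_genes else 1.0
    )
    summary["enrich"] = {
        "n_terms": len(records),
        "significant_terms": significant,
        "longevity_overlap_p": p_overlap,
    }


def _stage_report(config, outdir, state, summary):
    truth = state.get("selected_truth", set())
    psgs = state.get("psgs", set())
    fp = len(psgs - truth)
    summary["report"] = {
        "psg_count": len(psgs),
        "false_discoveries": fp,
        "fdp": fp / len(psgs) if psgs else 0.0,
    }


_RUNNERS = {
    "simulate": _stage_simulate,
    "orthologs": _stage_orthologs,
    "scan": _stage_scan,
    "expression": _stage_expression,
    "enrich": _stage_enrich,
    "report": _stage_report,
}
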