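"""One reproducible run: simulate -> DE -> signatures -> binding -> report.

The pipeline runs the stages in dependency order on either a simulated
dataset (with planted truth, in which case recovery metrics are scored) or
user-supplied files.  Every run directory receives the exact configuration
(with its hash) and per-stage TSV outputs; ``report.json`` aggregates all
summary fractions and test results and is byte-identical across reruns
with the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binding import (
    activator_repressor_overlap,
    associate_peaks,
    binding_enrichment,
    bound_genes,
    cres_per_gene,
    link_cres,
    merge_cres,
    non_changing_background,
    sharing_fraction,
    top_peaks,
)
from .diffexpr import DETable, PairwiseNB
from .io_formats import ExpressionMatrix, read_annotation, read_counts, read_peaks
from .signatures import ContrastCriterion, GeneSignature, SignatureRule, derive_signature
from .synthetic import DOMAINS, SimConfig, SyntheticTruth, emit_dataset, generate_truth, simulate_counts
from .targets import call_direct_targets, calls_frame, signature_correlation

logger = logging.getLogger("grnx")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Paths, thresholds and stage toggles for one pipeline run."""

    seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)

    # used when simulate is False
    counts_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    peak_paths: dict[str, str] = field(default_factory=dict)  # tf -> file
    truth_path: str | None = None

    # thresholds (single source of truth for every stage)
    alpha: float = 0.05
    lfc_min: float = 1.0
    max_distance: int = 100_000
    promoter_halfwidth: int = 1_000
    cre_halfwidth: int = 150
    top_n_peaks: int = 3_000
    signature_time_h: float = 36.0

    stages: tuple[str, ...] = (
        "simulate", "de", "signatures", "associate", "enrich", "targets",
        "cooccupancy", "report",
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _round_floats(obj, ndigits: int = 10):
    """Stable float formatting so report.json is byte-identical on reruns."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _f1(predicted: set[str], truth: set[str]) -> dict[str, float]:
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth) if truth else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_predicted": len(predicted), "n_truth": len(truth)}


def _jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return float("nan")
    return len(a & b) / len(a | b)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages and return (and optionally write) the report."""
    t_start = time.time()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.json", "w") as fh:
            json.dump(_round_floats(config.to_dict()), fh, sort_keys=True, indent=1,
                      default=str)

    stages = set(config.stages)
    report: dict = {
        "grnx_version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
    }

    # ---- inputs ----------------------------------------------------------
    truth: SyntheticTruth | None = None
    if config.simulate and "simulate" in stages:
        logger.info("stage simulate")
        truth = generate_truth(config.sim, seed=config.seed)
        matrix = simulate_counts(truth, seed=config.seed + 1)
        annotation = truth.annotation
        peaks_by_tf = {tf: list(p) for tf, p in truth.peaks.items()}
        if out is not None:
            emit_dataset(truth, out / "data", seed=config.seed + 1)
    else:
        for name, path in (("counts", config.counts_path),
                           ("metadata", config.metadata_path),
                           ("annotation", config.annotation_path)):
            if path is None or not Path(path).exists():
                raise PipelineError(
                    f"stage 'simulate' disabled and input {name!r} missing "
                    f"({path}); supply the file or enable simulation"
                )
        matrix = read_counts(config.counts_path, config.metadata_path)
        annotation = read_annotation(config.annotation_path)
        peaks_by_tf = {tf: read_peaks(p, tf) for tf, p in sorted(config.peak_paths.items())}
        if config.truth_path and Path(config.truth_path).exists():
            truth = SyntheticTruth.from_json(config.truth_path)

    domains = [d for d in DOMAINS if matrix.samples_for(d, config.signature_time_h)]
    induced_conditions = [c for c in matrix.conditions if "+" in c]
    t_sig = config.signature_time_h

    # ---- differential expression ----------------------------------------
    de_tables: dict[str, DETable] = {}
    if "de" in stages:
        logger.info("stage de")
        pairs = [(a, b) for i, a in enumerate(domains) for b in domains[i + 1:]]
        for a, b in pairs:
            key = f"{b}_vs_{a}@{t_sig:g}"
            de_tables[key] = PairwiseNB(matrix, a, b, t_sig, alpha=config.alpha,
                                        lfc_min=config.lfc_min).fit()
        for cond in induced_conditions:
            base = cond.split("+", 1)[0]
            key = f"{cond}_vs_{base}@{t_sig:g}"
            de_tables[key] = PairwiseNB(matrix, base, cond, t_sig,
                                        alpha=config.alpha,
                                        lfc_min=config.lfc_min).fit()
        if out is not None:
            (out / "de").mkdir(exist_ok=True)
            for key, table in de_tables.items():
                table.write(out / "de" / f"{key.replace('@', '_at_')}.tsv")
        report["de"] = {
            key: {"n_tested": len(t.frame), "n_up": len(t.genes("up")),
                  "n_down": len(t.genes("down"))}
            for key, t in sorted(de_tables.items())
        }
    elif {"signatures", "enrich", "targets"} & stages:
        raise PipelineError("stage 'de' disabled but downstream stages need its tables")

    # ---- signatures ------------------------------------------------------
    signatures: dict[str, GeneSignature] = {}
    if "signatures" in stages:
        logger.info("stage signatures")
        for d in domains:
            criteria = []
            for other in domains:
                if other == d:
                    continue
                key = f"{d}_vs_{other}@{t_sig:g}"
                if key in de_tables:
                    criteria.append(ContrastCriterion(key, "up"))
                else:
                    criteria.append(ContrastCriterion(f"{other}_vs_{d}@{t_sig:g}", "down"))
            rule = SignatureRule(d, tuple(criteria))
            signatures[d] = derive_signature(de_tables, rule, matrix)
        if out is not None:
            (out / "signatures").mkdir(exist_ok=True)
            for name, sig in signatures.items():
                with open(out / "signatures" / f"{name}.txt", "w") as fh:
                    fh.write("\n".join(sorted(sig.gene_ids)) + "\n")
        report["signatures"] = {n: len(s) for n, s in sorted(signatures.items())}
        if truth is not None:
            report["signature_jaccard"] = {
                d: _jaccard(set(signatures[d].gene_ids), truth.domain_set(d))
                for d in domains
            }

    # ---- peak association ------------------------------------------------
    links = []
    bound: dict[str, set[str]] = {}
    if "associate" in stages:
        logger.info("stage associate")
        all_peaks = []
        for tf, plist in sorted(peaks_by_tf.items()):
            all_peaks.extend(top_peaks(plist, config.top_n_peaks))
        links = associate_peaks(all_peaks, annotation, config.max_distance,
                                config.promoter_halfwidth)
        bound = {tf: bound_genes(links, tf) for tf in peaks_by_tf}
        if out is not None:
            frame = pd.DataFrame(
                {
                    "tf": [l.peak.tf for l in links],
                    "chrom": [l.peak.chrom for l in links],
                    "summit": [l.peak.summit for l in links],
                    "gene_id": [l.gene_id for l in links],
                    "signed_distance": [l.signed_distance for l in links],
                    "category": [l.category for l in links],
                }
            )
            frame.to_csv(out / "peak_gene_links.tsv", sep="\t", index=False)
        n_promoter = sum(1 for l in links if l.category == "promoter")
        report["associate"] = {
            "n_links": len(links),
            "fraction_distal": (1 - n_promoter / len(links)) if links else float("nan"),
            "bound_genes": {tf: len(g) for tf, g in sorted(bound.items())},
        }
    elif {"enrich", "targets", "cooccupancy"} & stages:
        raise PipelineError("stage 'associate' disabled but downstream stages need links")

    # ---- binding enrichment ---------------------------------------------
    if "enrich" in stages:
        logger.info("stage enrich")
        all_tested: set[str] = set()
        for table in de_tables.values():
            all_tested |= set(table.frame.index)
        enrich_report = {}
        for sig_name, sig in sorted(signatures.items()):
            if len(sig) == 0:
                continue
            nc_bg = non_changing_background(de_tables.values(), exclude=sig.gene_ids)
            all_bg = all_tested - sig.gene_ids
            per_tf = {}
            for tf in sorted(bound):
                entry = {}
                res_all = binding_enrichment(set(sig.gene_ids), all_bg, bound[tf],
                                             set_name=sig_name, tf=tf)
                entry["vs_all_genes"] = {
                    "set_fraction": res_all.set_fraction,
                    "bg_fraction": res_all.bg_fraction,
                    "chi2": res_all.chi2, "p": res_all.p,
                    "fisher_p": res_all.fisher_p,
                }
                if nc_bg:
                    res_nc = binding_enrichment(set(sig.gene_ids), nc_bg, bound[tf],
                                                set_name=sig_name, tf=tf)
                    entry["vs_non_changing"] = {
                        "set_fraction": res_nc.set_fraction,
                        "bg_fraction": res_nc.bg_fraction,
                        "chi2": res_nc.chi2, "p": res_nc.p,
                        "fisher_p": res_nc.fisher_p,
                    }
                per_tf[tf] = entry
            enrich_report[sig_name] = per_tf
        report["enrichment"] = enrich_report

    # ---- direct-target calling ------------------------------------------
    if "targets" in stages:
        logger.info("stage targets")
        targets_report = {}
        for cond in induced_conditions:
            base, tf = cond.split("+", 1)
            key = f"{cond}_vs_{base}@{t_sig:g}"
            table = de_tables[key]
            repressed = table.genes("down")
            sig = signatures.get(base)
            if sig is None or len(sig) == 0 or tf not in bound:
                continue
            nc_bg = non_changing_background(de_tables.values(), exclude=sig.gene_ids)
            calls, summary = call_direct_targets(sig, repressed, bound[tf], tf=tf,
                                                 background=nc_bg or None)
            entry = summary.as_dict()
            if out is not None:
                calls_frame(calls).to_csv(out / f"calls_{cond.replace('+', '_')}.tsv",
                                          sep="\t")
            if truth is not None:
                predicted = {c.gene_id for c in calls if c.call == "direct_repressed"}
                entry["recovery"] = _f1(predicted,
                                        truth.direct_targets(tf, sig.gene_ids))
            # does the induced transcriptome resemble the repressor's home
            # domain?  Correlate on the union of the base- and home-domain
            # signatures so the contrast between programs is visible
            home = next((d for d, p in dict(config.sim.primary_tf).items()
                         if p == tf), None) if config.simulate else None
            if home and home in signatures and base in domains:
                union = GeneSignature(
                    f"{base}+{home}",
                    sig.gene_ids | signatures[home].gene_ids,
                    SignatureRule(f"{base}+{home}", ()),
                )
                if len(union) >= 3:
                    reports = signature_correlation(
                        matrix, union, [(cond, home), (cond, base)], t_sig)
                    entry["correlation"] = {
                        f"{r.condition_a}~{r.condition_b}": r.r for r in reports
                    }
            targets_report[cond] = entry
        report["targets"] = targets_report

    # ---- CRE co-occupancy ------------------------------------------------
    if "cooccupancy" in stages:
        logger.info("stage cooccupancy")
        kept = {tf: top_peaks(p, config.top_n_peaks)
                for tf, p in sorted(peaks_by_tf.items())}
        cres = link_cres(merge_cres(kept, config.cre_halfwidth), annotation,
                         config.max_distance)
        hist, frac_ge3 = cres_per_gene(cres)
        cooc: dict = {
            "n_cres": len(cres),
            "fraction_genes_ge3_cres": frac_ge3,
        }
        pair_keys = (list(truth.planted_sharing) if truth is not None
                     else [f"{a}|{b}" for a in kept for b in kept if a != b])
        sharing = {}
        for key in sorted(pair_keys):
            a, b = key.split("|")
            if a in kept and b in kept:
                sharing[key] = sharing_fraction(cres, a, b)
        cooc["sharing"] = sharing
        if truth is not None:
            cooc["planted_sharing"] = dict(sorted(truth.planted_sharing.items()))
        sim = config.sim
        activators = {sim.sox_tf, sim.gli_tf} & set(kept)
        repressors = set(kept) - activators - {sim.decoy_tf}
        if activators and repressors:
            cooc["activator_repressor"] = activator_repressor_overlap(
                cres, activators, repressors)
        if out is not None:
            pd.DataFrame(
                {
                    "chrom": [c.chrom for c in cres],
                    "start": [c.start for c in cres],
                    "end": [c.end for c in cres],
                    "occupants": [",".join(sorted(c.occupants)) for c in cres],
                    "n_peaks": [c.n_peaks for c in cres],
                    "gene_id": [c.gene_id or "" for c in cres],
                }
            ).to_csv(out / "cres.tsv", sep="\t", index=False)
        report["cooccupancy"] = cooc

    report["runtime_s"] = round(time.time() - t_start, 3)
    report = _round_floats(report)
    if out is not None and "report" in stages:
        stable = dict(report)
        stable.pop("runtime_s")  # byte-identical reruns
        with open(out / "report.json", "w") as fh:
            json.dump(stable, fh, sort_keys=True, indent=1)
            fh.write("\n")
    return report
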