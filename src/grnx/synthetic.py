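"""Synthetic neural-progenitor dataset with a planted regulatory truth.

The generator emulates the study design the package is built for: four
progenitor-domain conditions (dorsal, pMN, p3, FP) sampled along a time
grid, TF-induction perturbations of a base condition, negative-binomial
gene counts, and ChIP-style peaks placed near planted target genes.

The planted network follows the "broad activation + dense cross-repression"
architecture: a pan-neural activator (Sox2-like) and a morphogen mediator
(Gli-like, ventral conditions only) switch genes on with staggered
early/intermediate/late onsets, while each domain's repressor TFs divide
the expression of every other domain's genes by ``fold_repression`` once
they come on.  A fraction of repressor->gene edges is *direct* (a peak is
planted within the association distance of the target TSS); the rest are
indirect (no peak).  Decoy peaks at random positions, and a decoy TF with
no regulatory role, exercise the false-positive side of every downstream
statistic.

Expression logic, per gene g in condition c at time t::

    mu(g, c, t) = baseline_g * activation(g, c, t)
                  / prod(fold_e for edges e = (tf, g) with tf active in (c, t))

where a repressor is active in its home domains from ``repressor_onset``
onwards and, for induced conditions, from the induction time onwards.
Counts are NB(mu * s_j, phi) with planted per-sample size factors.

Everything is reproducible: the truth is a pure function of (config, seed)
and the emitted dataset a pure function of (truth, replicates, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneAnnotation,
    Peak,
    SampleMeta,
    write_annotation,
    write_counts,
    write_peaks,
)

__all__ = ["SimConfig", "SyntheticTruth", "generate_truth", "simulate_counts",
           "emit_dataset"]

DOMAINS = ("dorsal", "pMN", "p3", "FP")
VENTRAL = ("pMN", "p3", "FP")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic experiment."""

    genes_per_domain: int = 200
    n_shared_ventral: int = 200
    # majority of the transcriptome is condition-stable, as in real data;
    # median-of-ratios normalization assumes most genes are non-DE
    n_housekeeping: int = 800
    time_grid: tuple[float, ...] = (12.0, 24.0, 36.0, 60.0)
    replicates: int = 3

    # domain rosters: which repressor TFs are expressed where
    rosters: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("dorsal", ("Pax7",)),
        ("pMN", ("Olig2", "Nkx6.1")),
        ("p3", ("Nkx2.2", "Nkx6.1")),
        ("FP", ("Foxa2",)),
    )
    # the TF whose edges implement each domain's cross-repression
    primary_tf: tuple[tuple[str, str], ...] = (
        ("dorsal", "Pax7"), ("pMN", "Olig2"), ("p3", "Nkx2.2"), ("FP", "Foxa2"),
    )
    # Nkx6.1-style secondary repressor: (tf, target domain, fraction of genes)
    secondary_edges: tuple[tuple[str, str, float], ...] = (
        ("Nkx6.1", "dorsal", 0.5), ("Nkx6.1", "FP", 0.5),
    )
    repressor_onset_index: int = 1  # repressors switch on at grid[1] (24 h)

    edge_prob: float = 1.0        # P(cross-domain repressor edge exists)
    direct_fraction: float = 0.7  # P(edge is direct | edge)
    fold_repression: float = 8.0

    baseline_mean: float = 200.0
    baseline_sigma: float = 0.5
    baseline_min: float = 50.0
    off_level: float = 0.05       # activation floor before onset / without input
    onset_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)  # early/int/late
    dispersion: float = 0.05
    size_factor_sigma: float = 0.15

    inductions: tuple[tuple[str, str, float], ...] = (("pMN", "Nkx2.2", 12.0),)
    # after induction + this delay the induced repressor has shut off the
    # resident domain TFs and the cell runs the induced TF's home-domain
    # roster (selection by exclusion); None disables the identity switch
    roster_switch_delay_h: float | None = 12.0

    # peaks
    promoter_fraction: float = 0.2
    distal_min: int = 2_000
    distal_max: int = 20_000
    peak_halfwidth: int = 200
    decoy_fraction: float = 0.3
    decoy_tf: str = "decoyTF"
    n_decoy_tf_peaks: int = 200
    sox_tf: str = "Sox2"
    gli_tf: str = "Gli1"
    sox_peak_prob: float = 0.8
    gli_peak_prob: float = 0.7
    # planted CRE co-placement fractions: (tfA, tfB, fraction of tfA peaks
    # placed at tfB's summit when both bind the same gene)
    coplacement: tuple[tuple[str, str, float], ...] = (
        ("Nkx2.2", "Sox2", 0.22), ("Olig2", "Nkx2.2", 0.53),
        ("Nkx6.1", "Nkx2.2", 0.11), ("Gli1", "Sox2", 0.2),
    )
    min_peak_separation: int = 400  # keeps non-co-placed summits in distinct CREs

    tss_spacing: int = 50_000
    gene_body: int = 10_000
    chrom: str = "chr1"

    def roster_of(self, domain: str) -> tuple[str, ...]:
        return dict(self.rosters)[domain]

    @property
    def all_tfs(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, tfs in self.rosters:
            for tf in tfs:
                seen.setdefault(tf, None)
        return list(seen)

    def validate(self) -> None:
        primaries = dict(self.primary_tf)
        for domain, tf in primaries.items():
            if tf not in self.roster_of(domain):
                raise ValueError(f"primary TF {tf} absent from {domain} roster")
        expressed = {tf for _, tfs in self.rosters for tf in tfs}
        for tf, _, _ in self.secondary_edges:
            if tf not in expressed:
                raise ValueError(f"secondary repressor {tf} absent from all rosters")
        for base, tf, t_ind in self.inductions:
            if base not in dict(self.rosters):
                raise ValueError(f"induction base condition {base!r} unknown")
            if t_ind not in self.time_grid and t_ind > max(self.time_grid):
                raise ValueError("induction time beyond the grid")


@dataclass
class SyntheticTruth:
    """Planted structure the pipeline is scored against."""

    config: SimConfig
    seed: int
    genes: pd.DataFrame           # index gene_id: domain, baseline, onset_time
    annotation: list[GeneAnnotation]
    edges: pd.DataFrame           # tf, gene_id, direct, fold
    activator_inputs: pd.DataFrame  # activator, gene_id, onset_time
    peaks: dict[str, list[Peak]]
    planted_sharing: dict[str, float]   # "tfA|tfB" -> co-placed fraction
    size_factors: pd.Series             # per sample name

    # -- derived views -----------------------------------------------------

    def domain_set(self, domain: str) -> set[str]:
        return set(self.genes.index[self.genes["domain"] == domain])

    def direct_targets(self, tf: str, restrict: set[str] | None = None) -> set[str]:
        sel = self.edges[(self.edges["tf"] == tf) & self.edges["direct"]]
        out = set(sel["gene_id"])
        return out if restrict is None else out & restrict

    def repressed_targets(self, tf: str, restrict: set[str] | None = None) -> set[str]:
        sel = self.edges[self.edges["tf"] == tf]
        out = set(sel["gene_id"])
        return out if restrict is None else out & restrict

    @property
    def conditions(self) -> list[str]:
        conds = list(DOMAINS)
        for base, tf, _ in self.config.inductions:
            conds.append(f"{base}+{tf}")
        return conds

    def _active_tfs(self, condition: str, time_h: float) -> set[str]:
        cfg = self.config
        onset = cfg.time_grid[cfg.repressor_onset_index]
        if "+" in condition:
            base, induced = condition.split("+", 1)
        else:
            base, induced = condition, None
        roster = cfg.roster_of(base)
        if induced is not None:
            t_ind = {(b, tf): t for b, tf, t in cfg.inductions}[(base, induced)]
            home = next((d for d, p in dict(cfg.primary_tf).items() if p == induced),
                        None)
            switched = (cfg.roster_switch_delay_h is not None and home is not None
                        and time_h >= t_ind + cfg.roster_switch_delay_h)
            if switched:
                roster = cfg.roster_of(home)
            active = {tf for tf in roster if time_h >= onset}
            if time_h >= t_ind:
                active.add(induced)
            return active
        return {tf for tf in roster if time_h >= onset}

    def mu(self, condition: str, time_h: float) -> pd.Series:
        """Expected normalized expression of every gene in one cell."""
        cfg = self.config
        base = condition.split("+", 1)[0]
        active = self._active_tfs(condition, time_h)
        baseline = self.genes["baseline"].to_numpy()
        onset = self.genes["onset_time"].to_numpy()
        needs_gli = self.genes["gli_input"].to_numpy(dtype=bool)
        act_present = np.where(needs_gli, base in VENTRAL, True)
        activation = np.where((time_h >= onset) & act_present, 1.0, cfg.off_level)
        mu = baseline * activation
        if active:
            rep = self.edges[self.edges["tf"].isin(active)]
            if len(rep):
                divide = rep.groupby("gene_id")["fold"].prod()
                factor = divide.reindex(self.genes.index).fillna(1.0).to_numpy()
                mu = mu / factor
        return pd.Series(mu, index=self.genes.index, name=f"{condition}@{time_h:g}h")

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "seed": self.seed,
            "genes": self.genes.reset_index().to_dict(orient="list"),
            "annotation": [asdict(g) for g in self.annotation],
            "edges": self.edges.to_dict(orient="list"),
            "activator_inputs": self.activator_inputs.to_dict(orient="list"),
            "peaks": {
                tf: [asdict(p) for p in plist] for tf, plist in self.peaks.items()
            },
            "planted_sharing": self.planted_sharing,
            "size_factors": self.size_factors.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=None, sort_keys=True, default=_jsonify)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        raw_cfg = payload["config"]
        for key, value in raw_cfg.items():
            if isinstance(value, list):
                raw_cfg[key] = _tuplify(value)
        config = SimConfig(**raw_cfg)
        genes = pd.DataFrame(payload["genes"]).set_index("gene_id")[
            ["domain", "baseline", "onset_time", "gli_input"]]
        return cls(
            config=config,
            seed=payload["seed"],
            genes=genes,
            annotation=[GeneAnnotation(**g) for g in payload["annotation"]],
            edges=pd.DataFrame(payload["edges"])[["tf", "gene_id", "direct", "fold"]],
            activator_inputs=pd.DataFrame(payload["activator_inputs"])[
                ["activator", "gene_id", "onset_time"]],
            peaks={tf: [Peak(**p) for p in plist]
                   for tf, plist in payload["peaks"].items()},
            planted_sharing=payload["planted_sharing"],
            size_factors=pd.Series(payload["size_factors"]),
        )


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _tuplify(value):
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    return value


# ---------------------------------------------------------------------------
# truth generation
# ---------------------------------------------------------------------------

def generate_truth(config: SimConfig = SimConfig(), seed: int = 0) -> SyntheticTruth:
    """Build the planted GRN, gene annotation and peak placements."""
    config.validate()
    rng = np.random.default_rng(seed)
    cfg = config
    primaries = dict(cfg.primary_tf)

    # genes ------------------------------------------------------------
    records = []
    for domain in DOMAINS:
        for i in range(cfg.genes_per_domain):
            records.append((f"{domain}_g{i:03d}", domain))
    for i in range(cfg.n_shared_ventral):
        records.append((f"ventral_g{i:03d}", "shared_ventral"))
    for i in range(cfg.n_housekeeping):
        records.append((f"hk_g{i:03d}", "housekeeping"))
    gene_ids = [g for g, _ in records]
    domains = [d for _, d in records]
    n = len(records)

    baseline = np.exp(rng.normal(np.log(cfg.baseline_mean), cfg.baseline_sigma, n))
    baseline = np.maximum(baseline, cfg.baseline_min)
    onset_idx = rng.choice([0, 1, 2], size=n, p=cfg.onset_probs)
    onset_time = np.array([cfg.time_grid[i] for i in onset_idx])
    is_hk = np.array([d == "housekeeping" for d in domains])
    onset_time[is_hk] = cfg.time_grid[0]  # housekeeping genes are always on

    # activator inputs: Sox2-like everywhere; Gli-like for ventral programs
    gli_input = np.array([d in ("pMN", "p3", "FP", "shared_ventral")
                          for d in domains])
    genes = pd.DataFrame(
        {
            "domain": domains,
            "baseline": baseline,
            "onset_time": onset_time,
            "gli_input": gli_input,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    act_rows = []
    for g, gli in zip(gene_ids, gli_input):
        if not genes.loc[g, "domain"] == "housekeeping":
            act_rows.append((cfg.sox_tf, g, float(genes.loc[g, "onset_time"])))
        if gli:
            act_rows.append((cfg.gli_tf, g, float(genes.loc[g, "onset_time"])))
    activator_inputs = pd.DataFrame(act_rows,
                                    columns=["activator", "gene_id", "onset_time"])

    # repressor edges ---------------------------------------------------
    edge_rows = []
    for g, d in zip(gene_ids, domains):
        if d == "housekeeping":
            continue
        if d == "shared_ventral":
            foreign = ["dorsal"]
        else:
            foreign = [dom for dom in DOMAINS if dom != d]
        for dom in foreign:
            tf = primaries[dom]
            if rng.random() < cfg.edge_prob:
                direct = bool(rng.random() < cfg.direct_fraction)
                edge_rows.append((tf, g, direct, cfg.fold_repression))
    # secondary repressor edges (Nkx6.1-style, partial coverage)
    for tf, target_domain, frac in cfg.secondary_edges:
        candidates = [g for g, d in zip(gene_ids, domains) if d == target_domain]
        chosen = rng.choice(candidates, size=int(round(frac * len(candidates))),
                            replace=False)
        for g in sorted(chosen):
            direct = bool(rng.random() < cfg.direct_fraction)
            edge_rows.append((tf, g, direct, cfg.fold_repression))
    edges = pd.DataFrame(edge_rows, columns=["tf", "gene_id", "direct", "fold"])

    # annotation: one chromosome, evenly spaced TSSs, alternating strands
    annotation = []
    tss_of = {}
    for i, g in enumerate(gene_ids):
        tss = 100_000 + i * cfg.tss_spacing
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            start, end = tss, tss + cfg.gene_body
        else:
            start, end = tss - cfg.gene_body + 1, tss + 1
        annotation.append(GeneAnnotation(g, cfg.chrom, strand, tss, start, end))
        tss_of[g] = tss
    chrom_len = 100_000 + n * cfg.tss_spacing

    # peak placement ----------------------------------------------------
    coplace = {(a, b): f for a, b, f in cfg.coplacement}
    placed: dict[str, list[tuple[str, int, bool]]] = {}  # gene -> [(tf, summit, coplaced)]
    peaks: dict[str, list[Peak]] = {}
    coplaced_count: dict[tuple[str, str], int] = {}
    total_count: dict[str, int] = {}

    def _sample_offset(gene: str) -> int:
        """Offset from TSS, rejected until clear of peaks already on the gene."""
        for _ in range(200):
            if rng.random() < cfg.promoter_fraction:
                off = int(rng.integers(-1_000, 1_001))
            else:
                mag = int(rng.integers(cfg.distal_min, cfg.distal_max + 1))
                off = mag if rng.random() < 0.5 else -mag
            summit = tss_of[gene] + off
            if all(abs(summit - s) >= cfg.min_peak_separation
                   for _, s, _ in placed.get(gene, [])):
                return summit
        raise RuntimeError("could not separate peak summits")  # pragma: no cover

    def _place(tf: str, gene: str) -> None:
        partner_summit = None
        was_coplaced = False
        for (a, b), f in coplace.items():
            if a != tf:
                continue
            partners = [s for t, s, _ in placed.get(gene, []) if t == b]
            if partners and rng.random() < f:
                partner_summit = partners[0]
                coplaced_count[(a, b)] = coplaced_count.get((a, b), 0) + 1
                was_coplaced = True
                break
        summit = partner_summit if partner_summit is not None else _sample_offset(gene)
        placed.setdefault(gene, []).append((tf, summit, was_coplaced))
        total_count[tf] = total_count.get(tf, 0) + 1
        score = float(np.round(1.0 + rng.gamma(4.0, 2.0), 3))
        start = max(summit - cfg.peak_halfwidth, 0)
        peaks.setdefault(tf, []).append(
            Peak(cfg.chrom, start, summit + cfg.peak_halfwidth, summit, score, tf,
                 name=f"{tf}_{gene}")
        )

    direct_by_tf = {
        tf: sorted(edges[(edges["tf"] == tf) & edges["direct"]]["gene_id"])
        for tf in cfg.all_tfs
    }
    # activator peaks: Sox2-like near most genes, Gli-like near its inputs
    activator_targets: dict[str, list[str]] = {cfg.sox_tf: [], cfg.gli_tf: []}
    for g in gene_ids:
        if genes.loc[g, "domain"] != "housekeeping" and rng.random() < cfg.sox_peak_prob:
            activator_targets[cfg.sox_tf].append(g)
        if genes.loc[g, "gli_input"] and rng.random() < cfg.gli_peak_prob:
            activator_targets[cfg.gli_tf].append(g)

    # deterministic placement order: topological on the co-placement pairs,
    # so each TF that may copy a partner's summit is placed after it
    all_peak_tfs = list(dict.fromkeys([cfg.sox_tf, cfg.gli_tf] + cfg.all_tfs))
    deps = {
        t: {b for a, b, _ in cfg.coplacement if a == t and b in all_peak_tfs}
        for t in all_peak_tfs
    }
    tf_order: list[str] = []
    pending = list(all_peak_tfs)
    while pending:
        ready = [t for t in pending if deps[t] <= set(tf_order)]
        if not ready:
            raise ValueError("cyclic co-placement configuration")
        tf_order.extend(ready)
        pending = [t for t in pending if t not in ready]
    for tf in tf_order:
        for g in activator_targets.get(tf, direct_by_tf.get(tf, [])):
            _place(tf, g)

    # decoy peaks: random positions for every real TF + the decoy-only TF
    for tf in list(peaks):
        n_decoy = int(round(cfg.decoy_fraction * len(peaks[tf])))
        for _ in range(n_decoy):
            summit = int(rng.integers(cfg.peak_halfwidth, chrom_len))
            score = float(np.round(1.0 + rng.gamma(4.0, 2.0), 3))
            peaks[tf].append(
                Peak(cfg.chrom, summit - cfg.peak_halfwidth,
                     summit + cfg.peak_halfwidth, summit, score, tf, name=f"{tf}_decoy")
            )
    decoy_list = []
    for _ in range(cfg.n_decoy_tf_peaks):
        summit = int(rng.integers(cfg.peak_halfwidth, chrom_len))
        score = float(np.round(1.0 + rng.gamma(4.0, 2.0), 3))
        decoy_list.append(
            Peak(cfg.chrom, summit - cfg.peak_halfwidth, summit + cfg.peak_halfwidth,
                 summit, score, cfg.decoy_tf, name=f"{cfg.decoy_tf}_decoy")
        )
    peaks[cfg.decoy_tf] = decoy_list
    for tf in peaks:
        peaks[tf].sort(key=lambda p: (p.chrom, p.start, p.end))

    # planted sharing = co-placed fraction over ALL of tfA's peaks (decoys
    # included — they are part of the placement the pipeline will measure)
    planted_sharing = {
        f"{a}|{b}": coplaced_count.get((a, b), 0) / len(peaks[a])
        for (a, b) in coplace
        if peaks.get(a)
    }

    # planted per-sample size factors (geometric mean 1 within the study)
    sample_names = []
    for cond in list(DOMAINS) + [f"{b}+{t}" for b, t, _ in cfg.inductions]:
        for t in cfg.time_grid:
            for r in range(1, cfg.replicates + 1):
                sample_names.append(f"{cond}_{t:g}h_r{r}")
    log_sf = rng.normal(0.0, cfg.size_factor_sigma, len(sample_names))
    log_sf -= log_sf.mean()
    size_factors = pd.Series(np.exp(log_sf), index=sample_names)

    return SyntheticTruth(
        config=cfg, seed=seed, genes=genes, annotation=annotation, edges=edges,
        activator_inputs=activator_inputs, peaks=peaks,
        planted_sharing=planted_sharing, size_factors=size_factors,
    )


# ---------------------------------------------------------------------------
# count emission
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi < 1e-8:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(truth: SyntheticTruth, replicates: int | None = None,
                    seed: int = 0) -> ExpressionMatrix:
    """Draw the NB count matrix implied by the truth (deterministic in seed)."""
    cfg = truth.config
    replicates = cfg.replicates if replicates is None else replicates
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    induction_time = {f"{b}+{t}": ti for b, t, ti in cfg.inductions}
    cols = {}
    metas = []
    for cond in truth.conditions:
        for t in cfg.time_grid:
            mu = truth.mu(cond, t).to_numpy()
            for r in range(1, replicates + 1):
                name = f"{cond}_{t:g}h_r{r}"
                sf = float(truth.size_factors.get(name, 1.0))
                cols[name] = _nb_draw(rng, mu * sf, cfg.dispersion)
                induced = cond.split("+", 1)[1] if "+" in cond else None
                metas.append(
                    SampleMeta(
                        sample=name, condition=cond, time_h=t, replicate=r,
                        induced_tf=induced,
                        induction_time_h=induction_time.get(cond),
                    )
                )
    counts = pd.DataFrame(cols, index=truth.genes.index.copy())
    return ExpressionMatrix(counts, metas)


def emit_dataset(truth: SyntheticTruth, outdir: str | Path,
                 replicates: int | None = None, seed: int = 0) -> dict[str, Path]:
    """Write counts/metadata/peaks/annotation/truth files; byte-stable in seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = simulate_counts(truth, replicates, seed)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.json",
    }
    write_counts(matrix, paths["counts"], paths["metadata"])
    write_annotation(truth.annotation, paths["annotation"])
    truth.to_json(paths["truth"])
    for tf, plist in sorted(truth.peaks.items()):
        p = outdir / f"peaks_{tf}.narrowPeak"
        write_peaks(plist, p)
        paths[f"peaks_{tf}"] = p
    return paths
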