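"""End-to-end orchestration: simulate/ingest -> annotate -> quantify ->
survival screen -> DE -> target consensus -> network -> figure stats,
with a manifest of thresholds, seeds and per-stage row counts."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import de as de_mod
from . import figstats, network, survival, targets
from . import simulate as sim_mod
from .core import IsomiRKey

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}/{code}] {message}")


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    alpha: float = 0.05
    dead_fraction: float = 0.5
    de_adj_p: float = 0.01
    min_support: int = 3
    top_fraction: float = 0.05
    z_threshold: float = 2.0
    min_degree: int = 2
    ties: str = "efron"
    simulate: bool = True
    sim: sim_mod.SimConfig = field(default_factory=sim_mod.SimConfig)
    # user-data paths, used when simulate is False
    gff3: str | None = None
    isoform_dir: str | None = None
    gene_counts: str | None = None
    clinical: str | None = None
    prediction_dir: str | None = None
    gmt: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.min_support < 1 or self.min_degree < 0:
            raise ValueError("invalid min_support/min_degree")


def _tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "thresholds": {
        "alpha": config.alpha, "dead_fraction": config.dead_fraction,
        "de_adj_p": config.de_adj_p, "min_support": config.min_support,
        "top_fraction": config.top_fraction, "z_threshold": config.z_threshold,
        "min_degree": config.min_degree, "ties": config.ties,
    }}

    # --- inputs -----------------------------------------------------------
    truth = None
    if config.simulate:
        sim_cfg = sim_mod.SimConfig(**{**asdict(config.sim), "seed": config.seed})
        sim = sim_mod.simulate_all(sim_cfg, out / "inputs")
        truth = sim.truth
        gff3, iso_dir = sim.gff3, sim.isoform_dir
        gene_counts_path, clinical_path = sim.gene_counts, sim.clinical
        pred_dir, gmt_path = sim.prediction_dir, sim.gmt
        manifest["stages"]["simulate"] = {"n_samples": sim_cfg.n_tumor + sim_cfg.n_normal}
    else:
        for name in ("gff3", "isoform_dir", "gene_counts", "clinical"):
            if getattr(config, name) is None:
                raise StageError("inputs", "missing_path", f"{name} is required when simulate=False")
        gff3, iso_dir = Path(config.gff3), Path(config.isoform_dir)
        gene_counts_path, clinical_path = Path(config.gene_counts), Path(config.clinical)
        pred_dir = Path(config.prediction_dir) if config.prediction_dir else None
        gmt_path = Path(config.gmt) if config.gmt else None

    # --- annotate + quantify ---------------------------------------------
    try:
        records = ann_mod.parse_gff3(gff3)
        rows_per_sample = {}
        for path in sorted(Path(iso_dir).glob("*.txt")):
            sample = path.name.split(".")[0]
            rows_per_sample[sample] = ann_mod.read_isoform_table(path)
        groups = {s: ("normal" if s.upper().startswith("NORMAL") else "tumor")
                  for s in rows_per_sample}
        matrix = ann_mod.build_matrix(rows_per_sample, records, groups)
    except Exception as exc:
        raise StageError("quantify", "parse_failure", str(exc)) from exc
    _tsv(matrix.counts, out / "isomir_counts.tsv", index_label="key")
    _tsv(matrix.rpm, out / "isomir_rpm.tsv", index_label="key")
    if len(matrix.skip_report):
        _tsv(matrix.skip_report, out / "skip_report.tsv", index=False)
    manifest["stages"]["quantify"] = {
        "n_keys": matrix.counts.shape[0],
        "n_samples": matrix.counts.shape[1],
        "n_skipped_rows": int(len(matrix.skip_report)),
    }

    # --- survival screen --------------------------------------------------
    clinical = survival.load_clinical(clinical_path)
    tumor_cols = [s for s in matrix.samples if matrix.sample_groups[s] == "tumor"]
    try:
        screen_tbl = survival.screen(
            matrix.rpm[tumor_cols], matrix.counts[tumor_cols], clinical,
            alpha=config.alpha, dead_fraction=config.dead_fraction, ties=config.ties,
        )
    except Exception as exc:
        raise StageError("survival", "fit_failure", str(exc)) from exc
    _tsv(screen_tbl, out / "survival_screen.tsv", index=False)
    summary = survival.screen_summary(screen_tbl)
    manifest["stages"]["survival"] = {"n_tested": len(screen_tbl), **summary}
    classes = dict(zip(screen_tbl["key"], screen_tbl["class"]))

    # --- differential expression -----------------------------------------
    try:
        kept = list(screen_tbl["key"])
        iso_log = de_mod.normalize_uq(matrix.counts.loc[kept] if kept else matrix.counts)
        iso_de = de_mod.moderated_t(
            iso_log, matrix.sample_groups, ("tumor", "normal"),
            adj_threshold=config.de_adj_p,
        )
        gene_counts = pd.read_csv(gene_counts_path, sep="\t", index_col=0)
        gene_log = de_mod.normalize_tmm(gene_counts)
        gene_groups = pd.Series(
            {s: ("normal" if s.upper().startswith("NORMAL") else "tumor")
             for s in gene_counts.columns}
        )
        gene_de = de_mod.moderated_t(
            gene_log, gene_groups, ("tumor", "normal"), adj_threshold=config.de_adj_p
        )
    except Exception as exc:
        raise StageError("de", "model_failure", str(exc)) from exc
    _tsv(iso_de, out / "isomir_de.tsv")
    _tsv(gene_de, out / "gene_de.tsv")
    manifest["stages"]["de"] = {
        "n_isomirs": len(iso_de),
        "isomir_up": int((iso_de["direction"] == "up").sum()),
        "isomir_down": int((iso_de["direction"] == "down").sum()),
        "n_genes": len(gene_de),
        "gene_up": int((gene_de["direction"] == "up").sum()),
        "gene_down": int((gene_de["direction"] == "down").sum()),
    }

    # --- target consensus -------------------------------------------------
    if pred_dir is not None:
        tables = [targets.read_prediction_table(p) for p in sorted(Path(pred_dir).glob("*.tsv"))]
        pairs = targets.consensus(tables, config.min_support)
        bins = targets.classify_pairs(pairs, iso_de, gene_de, classes)
        counts_tbl = targets.pair_bin_counts(bins)
        _tsv(counts_tbl, out / "target_pair_bins.tsv", index=False)
        pair_rows = pd.DataFrame(
            [{"key": p.key.label, "gene": p.gene, "support": p.support,
              "pair_class": p.pair_class} for p in pairs]
        )
        _tsv(pair_rows, out / "consensus_pairs.tsv", index=False)
        manifest["stages"]["targets"] = {
            "n_tables": len(tables),
            "n_consensus_pairs": len(pairs),
        }

    # --- co-expression network -------------------------------------------
    sig_keys = [k for k, c in classes.items() if c != survival.CLASS_NS]
    manifest["stages"]["network"] = {"n_nodes_in": len(sig_keys)}
    if len(sig_keys) >= 3:
        edges = network.correlation_edges(matrix.rpm[tumor_cols], sig_keys)
        try:
            edges, enrich = network.classify_pairs_correlation(
                edges, classes, config.z_threshold
            )
            _tsv(enrich, out / "correlation_enrichment.tsv", index=False)
        except ValueError as exc:
            log.warning("correlation classification skipped: %s", exc)
        graph = network.select_edges(edges, config.top_fraction, config.min_degree)
        _tsv(edges, out / "correlation_edges.tsv", index=False)
        manifest["stages"]["network"].update(
            n_edges=len(edges), n_selected_nodes=graph.number_of_nodes(),
            n_selected_edges=graph.number_of_edges(),
        )

    # --- figure statistics ------------------------------------------------
    keyed = [(IsomiRKey.parse(k), c) for k, c in classes.items()]
    shift_tbl = figstats.shift_preference(keyed)
    _tsv(shift_tbl, out / "shift_preference.tsv", index=False)

    protective = [k for k, c in classes.items() if c == survival.CLASS_PROTECTIVE]
    stats_summary = {}
    if len(protective) >= 2:
        grid = np.log2(matrix.rpm.loc[protective].to_numpy(dtype=float).T + 1.0)
        pca_res = figstats.pca(grid)
        labels = (matrix.sample_groups[matrix.samples] == "tumor").astype(int).to_numpy()
        if 0 < labels.sum() < len(labels):
            scores2 = pca_res.scores[:, :2]
            dist = np.sqrt(((scores2[:, None, :] - scores2[None, :, :]) ** 2).sum(-1))
            f_stat, perm_p = figstats.permanova(dist, labels, n_perm=999, seed=config.seed)
            roc = figstats.logistic_roc(scores2, labels)
            stats_summary = {
                "permanova_F": f_stat, "permanova_p": perm_p,
                "auc_tumor_vs_normal": roc.auc,
            }
    manifest["stages"]["figstats"] = stats_summary

    if gmt_path is not None:
        sets = figstats.read_gmt(gmt_path)
        universe = set(gene_de.index)
        query = set(gene_de.index[gene_de["direction"] == "down"]) & universe
        if query:
            enrich_tbl = figstats.ora(query, sets, universe)
            _tsv(enrich_tbl, out / "ora_down_genes.tsv", index=False)
            manifest["stages"]["ora"] = {"n_sets": len(sets), "n_query": len(query)}

    # --- recovery metrics against planted truth ---------------------------
    if truth is not None:
        manifest["recovery"] = recovery_metrics(truth, screen_tbl, iso_de, gene_de,
                                                pairs if pred_dir else None)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=float))
    return manifest


def recovery_metrics(truth, screen_tbl, iso_de, gene_de, pairs) -> dict:
    """Planted-truth recovery: survival sign accuracy, DE power, consensus."""
    classes = dict(zip(screen_tbl["key"], screen_tbl["class"]))
    planted = sorted(truth.protective_keys | truth.harmful_keys)
    correct = 0
    for label in planted:
        want = survival.CLASS_PROTECTIVE if label in truth.protective_keys else survival.CLASS_HARMFUL
        if classes.get(label) == want:
            correct += 1
    sign_acc = correct / len(planted) if planted else float("nan")

    de_hits = 0
    de_planted = sorted(truth.de_up_isomirs() | truth.de_down_isomirs())
    for label in de_planted:
        want = "up" if label in truth.de_up else "down"
        if label in iso_de.index and iso_de.loc[label, "direction"] == want:
            de_hits += 1
    de_power = de_hits / len(de_planted) if de_planted else float("nan")

    gene_hits = 0
    gene_planted = sorted(truth.de_up_genes() | truth.de_down_genes())
    for g in gene_planted:
        want = "up" if g in truth.de_up else "down"
        if g in gene_de.index and gene_de.loc[g, "direction"] == want:
            gene_hits += 1
    gene_power = gene_hits / len(gene_planted) if gene_planted else float("nan")

    out = {
        "survival_sign_accuracy": sign_acc,
        "isomir_de_power": de_power,
        "gene_de_power": gene_power,
    }
    if pairs is not None:
        found = {(p.key.label, p.gene) for p in pairs}
        tp = len(found & truth.true_pairs)
        out["consensus_recall"] = tp / len(truth.true_pairs) if truth.true_pairs else float("nan")
        out["consensus_precision"] = tp / len(found) if found else float("nan")
    return out
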