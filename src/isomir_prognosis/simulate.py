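"""Synthetic input generator with planted ground truth.

Produces every file the pipeline consumes — miRBase-style GFF3 with a
genome FASTA, per-sample GDC-style isoform quantification tables, a gene
count matrix, a clinical table, predictor pair tables and a GMT — from a
single seeded configuration, so every downstream stage can be tested
offline against known truth.

Counts are zero-inflated negative binomial (an assumption, flagged in the
manifest); block co-expression comes from a shared log-normal latent
factor per block; survival times follow an exponential-baseline
proportional-hazards model over the planted effects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import MatureRecord
from .core import IsomiRKey
from .targets import PredictionTable

MATURE_LEN = 22


@dataclass
class SimConfig:
    n_tumor: int = 60
    n_normal: int = 15
    n_hairpins: int = 12
    mature_per_hairpin: int = 2
    hairpin_length: int = 80
    shift_range: tuple[int, int] = (-3, 3)
    nb_dispersion: float = 0.25
    zero_rate: float = 0.08
    beta_effect: float = 0.8
    lfc: float = 1.5
    censor_rate: float = 0.3
    n_genes: int = 120
    n_blocks: int = 4
    block_sigma: float = 0.6
    n_protective: int = 4
    n_harmful: int = 4
    n_de: int = 6
    n_true_pairs: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_hairpins", "mature_per_hairpin",
                     "hairpin_length", "n_genes", "n_blocks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_normal < 0:
            raise ValueError("n_normal must be non-negative")
        if not 0 <= self.zero_rate < 1:
            raise ValueError("zero_rate must be in [0, 1)")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.shift_range[0] > self.shift_range[1]:
            raise ValueError("shift_range must be an inclusive (lo, hi) pair")
        if self.mature_per_hairpin * (MATURE_LEN + 8) > self.hairpin_length:
            raise ValueError("mature_per_hairpin does not fit in hairpin_length")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    protective_keys: set[str] = field(default_factory=set)
    harmful_keys: set[str] = field(default_factory=set)
    de_up: set[str] = field(default_factory=set)
    de_down: set[str] = field(default_factory=set)
    coexpr_blocks: dict[str, list[str]] = field(default_factory=dict)
    true_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_shifts: dict[str, list[int]] = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protective_keys & self.harmful_keys:
            raise ValueError("protective and harmful key sets must be disjoint")

    def de_up_isomirs(self) -> set[str]:
        return {f for f in self.de_up if "|" in f}

    def de_down_isomirs(self) -> set[str]:
        return {f for f in self.de_down if "|" in f}

    def de_up_genes(self) -> set[str]:
        return self.de_up - self.de_up_isomirs()

    def de_down_genes(self) -> set[str]:
        return self.de_down - self.de_down_isomirs()

    def to_json(self) -> str:
        payload = {
            "protective_keys": sorted(self.protective_keys),
            "harmful_keys": sorted(self.harmful_keys),
            "de_up": sorted(self.de_up),
            "de_down": sorted(self.de_down),
            "coexpr_blocks": {k: sorted(v) for k, v in sorted(self.coexpr_blocks.items())},
            "true_pairs": sorted(list(p) for p in self.true_pairs),
            "planted_shifts": {k: v for k, v in sorted(self.planted_shifts.items())},
            "notes": self.notes,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            protective_keys=set(d["protective_keys"]),
            harmful_keys=set(d["harmful_keys"]),
            de_up=set(d["de_up"]),
            de_down=set(d["de_down"]),
            coexpr_blocks=dict(d["coexpr_blocks"]),
            true_pairs={tuple(p) for p in d["true_pairs"]},
            planted_shifts={k: list(v) for k, v in d.get("planted_shifts", {}).items()},
            notes=d.get("notes", {}),
        )


@dataclass
class SimAnnotation:
    hairpins: list[tuple[str, str, str, int, int, str]]  # id, name, chrom, start, end, strand
    matures: list[MatureRecord]
    sequences: dict[str, str]

    def gff3_text(self) -> str:
        lines = ["##gff-version 3"]
        for hid, name, chrom, start, end, strand in self.hairpins:
            lines.append(
                f"{chrom}\t.\tmiRNA_primary_transcript\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={hid};Name={name}"
            )
            for m in self.matures:
                if m.hairpin_id == hid:
                    lines.append(
                        f"{m.chrom}\t.\tmiRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                        f"ID={m.accession};Name={m.name};Derives_from={hid}"
                    )
        return "\n".join(lines) + "\n"

    def fasta_text(self) -> str:
        out = []
        for chrom in sorted(self.sequences):
            out.append(f">{chrom}")
            seq = self.sequences[chrom]
            for i in range(0, len(seq), 70):
                out.append(seq[i : i + 70])
        return "\n".join(out) + "\n"


def generate_annotation(config: SimConfig) -> SimAnnotation:
    """Hairpin + mature records on both strands, with a genome-like store."""
    rng = config.rng(1)
    n_chrom = min(3, config.n_hairpins)
    cursors = {f"chr{i + 1}": 1000 for i in range(n_chrom)}
    hairpins = []
    matures: list[MatureRecord] = []
    acc_counter = 1
    for i in range(config.n_hairpins):
        chrom = f"chr{(i % n_chrom) + 1}"
        start = cursors[chrom]
        end = start + config.hairpin_length - 1
        cursors[chrom] = end + 60
        strand = "+" if i % 2 == 0 else "-"
        hid = f"MI{i + 1:07d}"
        hname = f"hsa-mir-s{i + 1}"
        hairpins.append((hid, hname, chrom, start, end, strand))
        arms = ["5p", "3p"][: config.mature_per_hairpin]
        for j, arm in enumerate(arms):
            if j == 0:
                m_start = start + 4
            else:
                m_start = end - 4 - (MATURE_LEN - 1)
            m_end = m_start + MATURE_LEN - 1
            matures.append(
                MatureRecord(
                    accession=f"MIMAT{acc_counter:07d}",
                    name=f"{hname.replace('mir', 'miR')}-{arm}",
                    chrom=chrom,
                    start=m_start,
                    end=m_end,
                    strand=strand,
                    hairpin_id=hid,
                )
            )
            acc_counter += 1
    sequences = {
        chrom: "".join(rng.choice(list("ACGT"), size=cursors[chrom] + 200))
        for chrom in sorted(cursors)
    }
    return SimAnnotation(hairpins=hairpins, matures=matures, sequences=sequences)


def _plant_keys(config: SimConfig, ann: SimAnnotation) -> tuple[list[tuple[MatureRecord, int]], GroundTruth]:
    """Choose the isomiR universe and plant the truth sets."""
    rng = config.rng(2)
    lo, hi = config.shift_range
    universe: list[tuple[MatureRecord, int]] = []
    for m in ann.matures:
        shifts = {0}
        candidates = [s for s in range(lo, hi + 1) if s != 0]
        n_extra = min(len(candidates), int(rng.integers(1, 3)))
        shifts.update(rng.choice(candidates, size=n_extra, replace=False).tolist())
        for s in sorted(shifts):
            universe.append((m, s))

    labels = [IsomiRKey(m.accession, s).label for m, s in universe]
    shifted_pos = [l for (m, s), l in zip(universe, labels) if s > 0]
    shifted_neg = [l for (m, s), l in zip(universe, labels) if s < 0]
    rng.shuffle(shifted_pos)
    rng.shuffle(shifted_neg)

    # protective keys biased toward positive shifts, harmful toward negative
    n_p, n_h = config.n_protective, config.n_harmful
    protective = set(shifted_pos[: max(1, int(round(n_p * 0.75)))])
    protective |= set(shifted_neg[: n_p - len(protective)])
    pool_neg = [l for l in shifted_neg if l not in protective]
    pool_pos = [l for l in shifted_pos if l not in protective]
    harmful = set(pool_neg[: max(1, int(round(n_h * 0.75)))])
    harmful |= set(pool_pos[: n_h - len(harmful)])

    remaining = [l for l in labels if l not in protective | harmful]
    rng.shuffle(remaining)
    de_up = set(remaining[: config.n_de])
    de_down = set(remaining[config.n_de : 2 * config.n_de])

    shuffled = list(labels)
    rng.shuffle(shuffled)
    blocks: dict[str, list[str]] = {f"block{b + 1}": [] for b in range(config.n_blocks)}
    for i, label in enumerate(shuffled):
        blocks[f"block{(i % config.n_blocks) + 1}"].append(label)

    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    gene_order = list(genes)
    rng.shuffle(gene_order)
    de_up_genes = set(gene_order[: config.n_de * 2])
    de_down_genes = set(gene_order[config.n_de * 2 : config.n_de * 4])

    n_pairs = min(config.n_true_pairs, len(labels) * len(genes))
    pair_idx = rng.choice(len(labels) * len(genes), size=n_pairs, replace=False)
    true_pairs = {(labels[i // len(genes)], genes[i % len(genes)]) for i in pair_idx}

    planted_shifts: dict[str, list[int]] = {}
    for m, s in universe:
        planted_shifts.setdefault(m.accession, []).append(s)

    truth = GroundTruth(
        protective_keys=protective,
        harmful_keys=harmful,
        de_up=de_up | de_up_genes,
        de_down=de_down | de_down_genes,
        coexpr_blocks=blocks,
        true_pairs=true_pairs,
        planted_shifts=planted_shifts,
        notes={"count_model": "zero-inflated negative binomial (assumed, not from data)"},
    )
    return universe, truth


def sample_names(config: SimConfig) -> tuple[list[str], list[str]]:
    tumor = [f"TUMOR_{i + 1:03d}" for i in range(config.n_tumor)]
    normal = [f"NORMAL_{i + 1:03d}" for i in range(config.n_normal)]
    return tumor, normal


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


@dataclass
class IsoformSim:
    tables: dict[str, pd.DataFrame]  # sample -> quantification table
    counts: pd.DataFrame  # isomiR labels x samples (planted truth counts)
    truth: GroundTruth
    universe: list[tuple[MatureRecord, int]]


def generate_isoform_files(config: SimConfig, ann: SimAnnotation) -> IsoformSim:
    """Per-sample quantification tables with planted counts.

    Counts are NB with a shared log-normal block factor and planted
    tumor/normal fold changes; each key's reads may split into several
    rows differing only at the 3' end, so aggregation is exercised.
    """
    universe, truth = _plant_keys(config, ann)
    rng = config.rng(3)
    tumor, normal = sample_names(config)
    samples = tumor + normal
    labels = [IsomiRKey(m.accession, s).label for m, s in universe]

    block_of = {}
    for bname, members in truth.coexpr_blocks.items():
        for l in members:
            block_of[l] = bname
    block_ids = sorted(truth.coexpr_blocks)

    base_mu = 2.0 ** rng.uniform(4.0, 7.0, size=len(labels))
    counts = np.zeros((len(labels), len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        is_tumor = sample in tumor
        factors = {b: math.exp(config.block_sigma * rng.normal()) for b in block_ids}
        mu = base_mu * np.array([factors[block_of[l]] for l in labels])
        if is_tumor:
            fold = np.ones(len(labels))
            for i, l in enumerate(labels):
                if l in truth.de_up:
                    fold[i] = 2.0**config.lfc
                elif l in truth.de_down:
                    fold[i] = 2.0**-config.lfc
            mu = mu * fold
        c = _nb_counts(rng, mu, config.nb_dispersion)
        if config.zero_rate > 0:
            c = c * (rng.random(len(labels)) >= config.zero_rate)
        counts[:, j] = c

    chrom_len = {c: len(s) for c, s in ann.sequences.items()}
    tables: dict[str, pd.DataFrame] = {}
    for j, sample in enumerate(samples):
        total = counts[:, j].sum()
        rows = []
        for i, (m, shift) in enumerate(universe):
            c = int(counts[i, j])
            if c == 0:
                continue
            # split into 3'-length variants to exercise key-level aggregation
            parts = [c] if c < 6 else [c - c // 3, c // 3]
            for part_idx, rc in enumerate(parts):
                ext = 2 * part_idx
                if m.strand == "+":
                    start = m.start + shift
                    end = min(m.end + ext, chrom_len[m.chrom])
                else:
                    end = m.end - shift
                    start = max(m.start - ext, 1)
                rpm = rc / total * 1e6
                rows.append(
                    {
                        "isoform_coords": f"hg38:{m.chrom}:{start}-{end}:{m.strand}",
                        "miRNA_region": f"mature,{m.accession}",
                        "read_count": rc,
                        "reads_per_million_miRNA_mapped": round(rpm, 6),
                        "miRNA_ID": m.accession,
                    }
                )
        tables[sample] = pd.DataFrame(
            rows,
            columns=["isoform_coords", "miRNA_region", "read_count",
                     "reads_per_million_miRNA_mapped", "miRNA_ID"],
        )
    counts_df = pd.DataFrame(counts, index=labels, columns=samples)
    return IsoformSim(tables=tables, counts=counts_df, truth=truth, universe=universe)


def generate_gene_counts(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Gene-level NB count matrix with planted tumor/normal fold changes."""
    rng = config.rng(4)
    tumor, normal = sample_names(config)
    samples = tumor + normal
    all_genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    base_mu = 2.0 ** rng.uniform(4.0, 9.0, size=len(all_genes))
    counts = np.zeros((len(all_genes), len(samples)), dtype=int)
    up, down = truth.de_up_genes(), truth.de_down_genes()
    for j, sample in enumerate(samples):
        mu = base_mu * math.exp(0.2 * rng.normal())
        if sample in tumor:
            fold = np.array(
                [2.0**config.lfc if g in up else 2.0**-config.lfc if g in down else 1.0
                 for g in all_genes]
            )
            mu = mu * fold
        counts[:, j] = _nb_counts(rng, mu, config.nb_dispersion)
    return pd.DataFrame(counts, index=all_genes, columns=samples)


T_STAGES = ["T1", "T2", "T3", "T4"]


def generate_clinical(
    config: SimConfig,
    rpm: pd.DataFrame,
    truth: GroundTruth,
) -> pd.DataFrame:
    """Clinical table for tumor samples under a proportional-hazards model.

    log-hazard = sum of planted beta times standardized log2(RPM+1)
    expression (negative beta for protective keys, positive for harmful)
    plus small confounder effects; exponential baseline; censoring by an
    independent uniform time calibrated to the requested rate.
    """
    rng = config.rng(5)
    tumor, _ = sample_names(config)
    tumor = [s for s in tumor if s in rpm.columns]
    n = len(tumor)

    age = np.round(rng.normal(65, 9, size=n), 1)
    cigs = np.round(np.abs(rng.normal(1.5, 1.2, size=n)), 2)
    t_stage = rng.choice(T_STAGES, size=n, p=[0.35, 0.35, 0.2, 0.1])
    t_score = np.array([int(t[1]) for t in t_stage])

    eta = 0.02 * (age - 65) + 0.05 * cigs + 0.15 * (t_score - 2)
    for label in sorted(truth.protective_keys | truth.harmful_keys):
        if label not in rpm.index:
            continue
        x = np.log2(rpm.loc[label, tumor].to_numpy(dtype=float) + 1.0)
        sd = x.std()
        if sd == 0:
            continue
        z = (x - x.mean()) / sd
        sign = -1.0 if label in truth.protective_keys else 1.0
        eta = eta + sign * config.beta_effect * z

    lam = 1e-3 * np.exp(eta)
    t_event = rng.exponential(1.0 / lam)
    u = rng.random(n)

    if config.censor_rate <= 0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        lo, hi = 1.0, float(t_event.max() * 10)
        for _ in range(200):  # calibrate uniform censor horizon to the target rate
            tau = 0.5 * (lo + hi)
            frac = np.mean(tau * u < t_event)
            if frac > config.censor_rate:
                lo = tau
            else:
                hi = tau
        tau = 0.5 * (lo + hi)
        c_time = tau * u
        event = (t_event <= c_time).astype(int)
        time = np.minimum(t_event, c_time)

    return pd.DataFrame(
        {
            "sample": tumor,
            "time": np.round(np.maximum(time, 0.5), 3),
            "event": event,
            "age_at_index": age,
            "cigarettes_per_day": cigs,
            "ajcc_pathologic_t": t_stage,
        }
    )


def generate_predictions(
    truth: GroundTruth,
    keys: list[str],
    genes: list[str],
    sensitivity: list[float],
    specificity: list[float],
    seed: int = 0,
) -> list[PredictionTable]:
    """One pair table per tool: true pairs at each tool's sensitivity plus
    false pairs at 1 - specificity."""
    if len(sensitivity) != len(specificity) or not sensitivity:
        raise ValueError("need matching, nonempty sensitivity/specificity lists")
    rng = np.random.default_rng([seed, 6])
    true_pairs = sorted(truth.true_pairs)
    false_pairs = sorted(
        (k, g) for k in keys for g in genes if (k, g) not in truth.true_pairs
    )
    tables = []
    for t, (sens, spec) in enumerate(zip(sensitivity, specificity)):
        pairs = {p for p in true_pairs if rng.random() < sens}
        fp_rate = 1.0 - spec
        if fp_rate > 0:
            pairs |= {p for p in false_pairs if rng.random() < fp_rate}
        tables.append(PredictionTable(tool=f"sim_tool_{t + 1}", pairs=pairs))
    return tables


def generate_gene_sets(config: SimConfig, truth: GroundTruth, n_sets: int = 8) -> dict[str, set[str]]:
    """GMT-style sets; the first is enriched in planted down-regulated genes."""
    rng = config.rng(7)
    all_genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    down = sorted(truth.de_down_genes())
    sets: dict[str, set[str]] = {}
    enriched = set(down[: max(3, len(down) // 2)])
    filler = rng.choice(all_genes, size=5, replace=False)
    sets["SET_PLANTED_DOWN"] = enriched | set(filler.tolist())
    for i in range(1, n_sets):
        size = int(rng.integers(8, 25))
        sets[f"SET_RANDOM_{i}"] = set(rng.choice(all_genes, size=size, replace=False).tolist())
    return sets


@dataclass
class SimOutput:
    root: Path
    gff3: Path
    fasta: Path
    isoform_dir: Path
    gene_counts: Path
    clinical: Path
    prediction_dir: Path
    gmt: Path
    truth_json: Path
    truth: GroundTruth
    annotation: SimAnnotation


def simulate_all(config: SimConfig, outdir: str | Path) -> SimOutput:
    """Generate and write the full synthetic input bundle."""
    root = Path(outdir)
    iso_dir = root / "isoforms"
    pred_dir = root / "predictions"
    iso_dir.mkdir(parents=True, exist_ok=True)
    pred_dir.mkdir(parents=True, exist_ok=True)

    ann = generate_annotation(config)
    (root / "annotation.gff3").write_text(ann.gff3_text())
    (root / "genome.fa").write_text(ann.fasta_text())

    iso = generate_isoform_files(config, ann)
    for sample, table in iso.tables.items():
        table.to_csv(iso_dir / f"{sample}.isoforms.quantification.txt", sep="\t", index=False)

    gene_counts = generate_gene_counts(config, iso.truth)
    gene_counts.to_csv(root / "gene_counts.tsv", sep="\t", index_label="gene")

    total = iso.counts.sum(axis=0)
    rpm = iso.counts / total.replace(0, np.nan) * 1e6
    clinical = generate_clinical(config, rpm.fillna(0.0), iso.truth)
    clinical.to_csv(root / "clinical.tsv", sep="\t", index=False)

    keys = list(iso.counts.index)
    genes = list(gene_counts.index)
    preds = generate_predictions(
        iso.truth, keys, genes,
        sensitivity=[0.9, 0.85, 0.8, 0.75],
        specificity=[0.999, 0.999, 0.998, 0.999],
        seed=config.seed,
    )
    for table in preds:
        df = pd.DataFrame(sorted(table.pairs), columns=["isomir", "gene"])
        df.to_csv(pred_dir / f"{table.tool}.tsv", sep="\t", index=False)

    sets = generate_gene_sets(config, iso.truth)
    with open(root / "gene_sets.gmt", "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + sorted(members)) + "\n")

    (root / "ground_truth.json").write_text(iso.truth.to_json())
    (root / "sim_config.json").write_text(json.dumps(asdict(config), indent=1, sort_keys=True))

    return SimOutput(
        root=root,
        gff3=root / "annotation.gff3",
        fasta=root / "genome.fa",
        isoform_dir=iso_dir,
        gene_counts=root / "gene_counts.tsv",
        clinical=root / "clinical.tsv",
        prediction_dir=pred_dir,
        gmt=root / "gene_sets.gmt",
        truth_json=root / "ground_truth.json",
        truth=iso.truth,
        annotation=ann,
    )
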