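"""Target-prediction consensus and regulatory pair classification.

External predictor outputs are ingested as minimal (isomiR label, gene)
pair tables; pairs supported by at least ``min_support`` tools survive.
A canonical seed-matcher is provided as a stand-in predictor for testing
only — it does not emulate any published scoring scheme.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import IsomiRKey, reverse_complement, to_rna
from .annotation import seed_of

log = logging.getLogger(__name__)

PAIR_UP_DOWN = "upIso_downGene"
PAIR_DOWN_UP = "downIso_upGene"
PAIR_OTHER = "other"


@dataclass
class PredictionTable:
    tool: str
    pairs: set[tuple[str, str]]  # (isomiR label, gene id)

    def __post_init__(self) -> None:
        for label, _gene in self.pairs:
            IsomiRKey.parse(label)  # validates the label dialect


def read_prediction_table(path: str | Path, tool: str | None = None) -> PredictionTable:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two columns (isomiR, gene)")
    cols = list(df.columns[:2])
    pairs = {(str(r[0]), str(r[1])) for r in df[cols].itertuples(index=False)}
    return PredictionTable(tool=tool or Path(path).stem, pairs=pairs)


@dataclass
class TargetPair:
    key: IsomiRKey
    gene: str
    support: int
    pair_class: str = PAIR_OTHER


def consensus(tables: list[PredictionTable], min_support: int = 3) -> list[TargetPair]:
    """Keep pairs predicted by at least ``min_support`` distinct tools."""
    names = [t.tool for t in tables]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate tool names: {names}")
    if min_support > len(tables):
        raise ValueError("min_support exceeds the number of tables")
    support: Counter[tuple[str, str]] = Counter()
    for t in tables:
        support.update(t.pairs)
    out = [
        TargetPair(key=IsomiRKey.parse(label), gene=gene, support=n)
        for (label, gene), n in support.items()
        if n >= min_support
    ]
    out.sort(key=lambda p: (p.key.accession, p.key.shift, p.gene))
    return out


def classify_pairs(
    pairs: list[TargetPair],
    isomir_de: pd.DataFrame,
    gene_de: pd.DataFrame,
    survival_classes: dict[str, str],
) -> dict[tuple[str, str], list[TargetPair]]:
    """Partition consensus pairs by survival class and DE-direction pattern.

    Returns bins keyed by (survival class, pair class); pairs whose
    isomiR or gene has no DE row land in the ("unresolved", "unresolved")
    bin. Bins are disjoint and jointly cover the input.
    """
    bins: dict[tuple[str, str], list[TargetPair]] = {}
    for pair in pairs:
        label = pair.key.label
        if label not in isomir_de.index or pair.gene not in gene_de.index:
            bins.setdefault(("unresolved", "unresolved"), []).append(pair)
            continue
        iso_dir = isomir_de.loc[label, "direction"]
        gene_dir = gene_de.loc[pair.gene, "direction"]
        if iso_dir == "up" and gene_dir == "down":
            pair.pair_class = PAIR_UP_DOWN
        elif iso_dir == "down" and gene_dir == "up":
            pair.pair_class = PAIR_DOWN_UP
        else:
            pair.pair_class = PAIR_OTHER
        sclass = survival_classes.get(label, "nonsignificant")
        bins.setdefault((sclass, pair.pair_class), []).append(pair)
    return bins


def pair_bin_counts(bins: dict[tuple[str, str], list[TargetPair]]) -> pd.DataFrame:
    rows = [
        {"survival_class": k[0], "pair_class": k[1], "n_pairs": len(v)}
        for k, v in sorted(bins.items())
    ]
    return pd.DataFrame(rows, columns=["survival_class", "pair_class", "n_pairs"])


def seed_sites(seq_rna: str) -> list[str]:
    """Canonical target sites for one isomiR sequence (5'->3' on the UTR).

    7mer-m8: complement of miRNA nt 2-8; 7mer-A1: complement of nt 2-7
    followed by A; 8mer: complement of nt 2-8 followed by A.
    """
    seed7 = seed_of(seq_rna)  # nt 2-8
    rc7 = reverse_complement(seed7)
    rc6 = reverse_complement(seq_rna[1:7])
    return [rc7 + "A", rc7, rc6 + "A"]


def seed_match_predict(
    sequences: dict[str, str],
    utrs: dict[str, str],
    tool: str = "seedmatch",
) -> PredictionTable:
    """Fixture predictor: report a pair when a UTR carries a canonical site."""
    utr_rna: dict[str, str] = {}
    for gene, utr in utrs.items():
        u = to_rna(utr)
        bad = set(u) - set("ACGU")
        if bad:
            raise ValueError(f"UTR {gene}: non-ACGU characters {sorted(bad)}")
        utr_rna[gene] = u
    pairs: set[tuple[str, str]] = set()
    for label, seq in sequences.items():
        sites = seed_sites(to_rna(seq))
        for gene, u in utr_rna.items():
            if any(site in u for site in sites):
                pairs.add((label, gene))
    return PredictionTable(tool=tool, pairs=pairs)


def jaccard(a: set, b: set) -> float:
    """|A∩B| / |A∪B|; defined as 0 when both sets are empty."""
    union = a | b
    if not union:
        log.info("jaccard of two empty sets: defined as 0")
        return 0.0
    return len(a & b) / len(union)
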