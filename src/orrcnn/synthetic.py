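"""Synthetic fixtures: random protein sequences, scored pairs with a planted
monotone structure, and a skip-gram corpus with planted co-occurrence.

The scored-pair generator plants a learnable signal: each protein draws its
own 7-class residue composition from a Dirichlet distribution, and the true
confidence score of a pair is the cosine similarity of the two composition
frequency vectors plus Gaussian noise, clipped strictly inside (0, 1). With
Dirichlet-spread compositions the cosine covers most of (0, 1), so the score
is a monotone function of a pair statistic the encoder can recover. (With
compositionally uniform sequences the cosine would collapse towards 1 and
nothing would be learnable; see docs/methods.md.)

These fixtures emulate scored pair tables such as STRING exports only in
format and score structure — not protein evolution, domain architecture or
interaction biophysics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data_io import ProteinRecord, ScoredPair, write_fasta, write_pair_table
from .embeddings import EH_CLASSES, eh_class_index


@dataclass(frozen=True)
class SyntheticConfig:
    """Desk-scale defaults: 300 sequences of length 50-120, 3000 pairs, K=5.

    ``composition_alpha`` is the symmetric Dirichlet concentration of the
    per-protein 7-class composition (smaller = spikier compositions = broader
    score spread). ``noise_sd`` is the s.d. of the Gaussian score noise;
    scores are clipped into [score_floor, score_ceiling] inside (0, 1).
    """

    n_sequences: int = 300
    length_range: tuple[int, int] = (50, 120)
    n_pairs: int = 3000
    K: int = 5
    noise_sd: float = 0.05
    seed: int = 0
    score_floor: float = 0.02
    score_ceiling: float = 0.98
    composition_alpha: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (50 <= lo <= hi <= 2000):
            raise ValueError("length_range must lie within [50, 2000]")
        if not 0.0 < self.score_floor < self.score_ceiling < 1.0:
            raise ValueError("need 0 < score_floor < score_ceiling < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def class_composition(record: ProteinRecord) -> np.ndarray:
    """7-class residue frequency vector of a sequence (unknowns ignored)."""
    idx = eh_class_index()
    counts = np.zeros(len(EH_CLASSES))
    for a in record.residues:
        ci = idx.get(a)
        if ci is not None:
            counts[ci] += 1
    total = counts.sum()
    return counts / total if total else counts


def composition_cosine(r1: ProteinRecord, r2: ProteinRecord) -> float:
    c1, c2 = class_composition(r1), class_composition(r2)
    n1, n2 = np.linalg.norm(c1), np.linalg.norm(c2)
    if n1 == 0 or n2 == 0:
        return 0.0
    return float(c1 @ c2 / (n1 * n2))


def gen_sequences(config: SyntheticConfig) -> list[ProteinRecord]:
    """Sequences with per-protein Dirichlet 7-class compositions.

    Each record draws class weights from Dirichlet(composition_alpha) and
    residues i.i.d. from those weights (uniform within a class); lengths are
    uniform over ``length_range``. Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    records = []
    for i in range(config.n_sequences):
        weights = rng.dirichlet(np.full(len(EH_CLASSES), config.composition_alpha))
        length = int(rng.integers(lo, hi + 1))
        classes = rng.choice(len(EH_CLASSES), size=length, p=weights)
        residues = "".join(
            EH_CLASSES[c][rng.integers(0, len(EH_CLASSES[c]))] for c in classes
        )
        records.append(ProteinRecord(id=f"SYN{i:05d}", residues=residues))
    return records


def gen_scored_pairs(
    records: list[ProteinRecord], config: SyntheticConfig
) -> list[ScoredPair]:
    """Uniformly sampled pairs scored by planted composition similarity.

    true score = clip(cos(composition_1, composition_2) + N(0, noise_sd),
    score_floor, score_ceiling).
    """
    if len(records) < 2:
        raise ValueError("need at least two records to form pairs")
    rng = np.random.default_rng(config.seed + 1)
    comps = np.stack([class_composition(r) for r in records])
    norms = np.linalg.norm(comps, axis=1)
    pairs = []
    for _ in range(config.n_pairs):
        i, j = rng.integers(0, len(records), size=2)
        cos = float(comps[i] @ comps[j] / (norms[i] * norms[j]))
        score = cos + rng.normal(0.0, config.noise_sd) if config.noise_sd else cos
        score = float(np.clip(score, config.score_floor, config.score_ceiling))
        pairs.append(ScoredPair(id1=records[i].id, id2=records[j].id, score=score))
    return pairs


def gen_skipgram_corpus(
    config: SyntheticConfig,
    planted: tuple[str, str] = ("A", "G"),
    avoided: tuple[str, str] = ("A", "W"),
    stickiness: float = 0.6,
) -> list[ProteinRecord]:
    """Sequences from biased bigram transitions so that the ``planted`` symbol
    pair co-occurs far above chance while the ``avoided`` pair never does.

    After either symbol of the planted pair, the next residue is the other
    planted symbol with probability ``stickiness``; the avoided partner is
    never emitted adjacent to the planted first symbol. All 20 symbols occur.
    """
    from .data_io import ALPHABET

    rng = np.random.default_rng(config.seed + 2)
    a, g = planted
    _, w = avoided
    lo, hi = config.length_range
    records = []
    for i in range(config.n_sequences):
        length = int(rng.integers(lo, hi + 1))
        chars = [ALPHABET[rng.integers(0, 20)]]
        for _ in range(length - 1):
            prev = chars[-1]
            if prev in (a, g) and rng.random() < stickiness:
                nxt = g if prev == a else a
            else:
                nxt = ALPHABET[rng.integers(0, 20)]
                while (prev == a and nxt == w) or (prev == w and nxt == a):
                    nxt = ALPHABET[rng.integers(0, 20)]
            chars.append(nxt)
        records.append(ProteinRecord(id=f"SG{i:05d}", residues="".join(chars)))
    return records


def write_fixture(outdir, config: SyntheticConfig) -> dict:
    """Emit FASTA + scored-pair TSV + a metadata JSON recording the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = gen_sequences(config)
    pairs = gen_scored_pairs(records, config)
    write_fasta(records, outdir / "sequences.fasta")
    write_pair_table(pairs, outdir / "pairs.tsv")
    meta = {
        "config": asdict(config),
        "n_sequences": len(records),
        "n_pairs": len(pairs),
        "planted_signal": "cosine similarity of 7-class composition vectors",
    }
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return meta
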