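"""Synthetic fixture generation with planted ground truth.

Every generator takes an explicit integer seed and is fully deterministic
(independent ``numpy`` Generator streams; no reliance on hash order). The
returned :class:`SimTruth` carries everything needed to score recall and
precision of the analysis modules without re-reading parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import AlignedRead, GenomicInterval
from .targets import reverse_complement

__all__ = [
    "SimTruth",
    "SimulationError",
    "simulate_clustered_reads",
    "simulate_pingpong_reads",
    "simulate_counts",
    "simulate_target_sequences",
]

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass
class SimTruth:
    """Planted ground truth for one simulation run."""

    seed: int
    params: dict = field(default_factory=dict)
    clusters: list[dict] = field(default_factory=list)
    pingpong_pairs: list[dict] = field(default_factory=list)
    de_table: list[dict] = field(default_factory=list)
    target_pairs: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_clustered_reads(
    chrom_len: int = 1_000_000,
    n_clusters: int = 3,
    reads_per_cluster: int = 50,
    intra_spacing_mean: float = 20.0,
    noise_reads: int = 100,
    seed: int = 0,
    read_len: int = 26,
    chrom: str = "chrS",
    dual_strand: bool = True,
) -> tuple[list[AlignedRead], SimTruth]:
    """Reads planted in dense blocks on a noisy background.

    Intra-cluster 5' spacings are geometric with the given mean; noise
    reads are uniform over the chromosome (background spacing mean =
    chrom_len / noise_reads). Cluster strand composition is mixed when
    ``dual_strand``, otherwise uniform per cluster (alternating +/-).
    """
    rng = np.random.default_rng(seed)
    span_estimate = int(reads_per_cluster * intra_spacing_mean * 3) + 2 * read_len
    if n_clusters * span_estimate * 2 > chrom_len:
        raise SimulationError(
            f"cannot pack {n_clusters} clusters of ~{span_estimate} bp "
            f"into {chrom_len} bp"
        )
    reads: list[AlignedRead] = []
    truth = SimTruth(
        seed=seed,
        params={
            "chrom_len": chrom_len,
            "n_clusters": n_clusters,
            "reads_per_cluster": reads_per_cluster,
            "intra_spacing_mean": intra_spacing_mean,
            "noise_reads": noise_reads,
            "read_len": read_len,
            "background_spacing_mean": (
                chrom_len / noise_reads if noise_reads else None
            ),
        },
    )
    segment = chrom_len // (n_clusters + 1) if n_clusters else chrom_len
    for ci in range(n_clusters):
        anchor = (ci + 1) * segment + int(rng.integers(0, max(segment // 4, 1)))
        spacings = rng.geometric(1.0 / intra_spacing_mean, size=reads_per_cluster - 1)
        five_primes = anchor + np.concatenate([[0], np.cumsum(spacings)])
        if dual_strand:
            strands = rng.choice(["+", "-"], size=reads_per_cluster)
            if len(set(strands)) == 1:  # force dual composition
                strands[0] = "+" if strands[0] == "-" else "-"
        else:
            strands = np.full(reads_per_cluster, "+" if ci % 2 == 0 else "-")
        members = []
        for ri, (p, st) in enumerate(zip(five_primes, strands)):
            members.append(_read_from_five_prime(
                chrom, int(p), st, read_len, f"cl{ci}_r{ri}"
            ))
        reads.extend(members)
        label = (
            "dual"
            if {"+", "-"} <= set(strands)
            else ("uni_plus" if strands[0] == "+" else "uni_minus")
        )
        truth.clusters.append(
            {
                "chrom": chrom,
                "start": min(m.interval.start for m in members),
                "end": max(m.interval.end for m in members),
                "n_reads": reads_per_cluster,
                "strandedness": label,
            }
        )
    noise_pos = rng.integers(read_len, chrom_len - read_len, size=noise_reads)
    noise_strand = rng.choice(["+", "-"], size=noise_reads)
    for ni, (p, st) in enumerate(zip(noise_pos, noise_strand)):
        reads.append(_read_from_five_prime(chrom, int(p), st, read_len, f"noise_r{ni}"))
    reads.sort(key=lambda r: (r.interval.start, r.read_id))
    return reads, truth


def _read_from_five_prime(
    chrom: str, p: int, strand: str, read_len: int, read_id: str
) -> AlignedRead:
    if strand == "+":
        iv = GenomicInterval(chrom, p, p + read_len, "+")
    else:
        iv = GenomicInterval(chrom, p - read_len + 1, p + 1, "-")
    return AlignedRead(iv, read_id)


def simulate_pingpong_reads(
    n_pairs: int,
    overlap_dist: Mapping[int, float] | None = None,
    read_len: int = 26,
    seed: int = 0,
    n_decoys: int = 0,
    chrom: str = "chrS",
) -> tuple[list[AlignedRead], SimTruth]:
    """Opposite-strand read pairs with exact requested 5' overlaps.

    Pair and decoy anchors are laid out on slots spaced 3 read lengths
    apart, so no cross-anchor pair can overlap and the planted pairs are
    exactly the overlapping pairs present.
    """
    if overlap_dist is None:
        overlap_dist = {10: 1.0}
    if any(L >= read_len or L < 1 for L in overlap_dist):
        raise ValueError("overlap lengths must be in [1, read_len)")
    rng = np.random.default_rng(seed)
    lens = np.array(sorted(overlap_dist))
    weights = np.array([overlap_dist[L] for L in lens], dtype=float)
    weights /= weights.sum()
    slot = 3 * read_len
    n_slots = n_pairs + n_decoys
    anchors = 2 * read_len + slot * rng.permutation(n_slots)
    reads: list[AlignedRead] = []
    truth = SimTruth(
        seed=seed,
        params={
            "n_pairs": n_pairs,
            "n_decoys": n_decoys,
            "read_len": read_len,
            "overlap_dist": {int(k): float(v) for k, v in overlap_dist.items()},
        },
    )
    for pi in range(n_pairs):
        a = int(anchors[pi])
        overlap = int(rng.choice(lens, p=weights))
        plus = _read_from_five_prime(chrom, a, "+", read_len, f"pp{pi}_plus")
        minus = _read_from_five_prime(
            chrom, a + overlap - 1, "-", read_len, f"pp{pi}_minus"
        )
        reads.extend([plus, minus])
        truth.pingpong_pairs.append(
            {
                "plus_id": plus.read_id,
                "minus_id": minus.read_id,
                "overlap": overlap,
            }
        )
    for di in range(n_decoys):
        a = int(anchors[n_pairs + di])
        st = rng.choice(["+", "-"])
        reads.append(_read_from_five_prime(chrom, a, st, read_len, f"decoy{di}"))
    reads.sort(key=lambda r: (r.interval.start, r.read_id))
    return reads, truth


def simulate_counts(
    n_pirnas: int = 500,
    n_samples: int = 6,
    library_size: int = 1_000_000,
    de_fraction: float = 0.1,
    lfc_mean: float = 2.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted differential expression.

    Samples split into control and test halves; DE features have their
    test-condition means shifted by the planted log2 fold change. Returns
    the counts and a truth table (id, log2fc, direction, kind).
    """
    if min(n_pirnas, n_samples, library_size) <= 0 or dispersion <= 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    ids = [f"sim_piRNA_{i + 1}" for i in range(n_pirnas)]
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_pirnas)
    n_de = int(round(de_fraction * n_pirnas))
    de_idx = rng.choice(n_pirnas, size=n_de, replace=False)
    lfc = rng.normal(lfc_mean, 0.25, size=n_de) * rng.choice([1.0, -1.0], size=n_de)
    fold = np.ones(n_pirnas)
    fold[de_idx] = 2.0 ** lfc
    n_ctrl = n_samples // 2
    p_ctrl = base / base.sum()
    shifted = base * fold
    p_test = shifted / shifted.sum()
    r = 1.0 / dispersion
    cols = {}
    for s in range(n_samples):
        p = p_ctrl if s < n_ctrl else p_test
        mu = p * library_size
        cols[("ctrl" if s < n_ctrl else "test") + f"_{s + 1}"] = (
            rng.negative_binomial(r, r / (r + mu))
        )
    counts = pd.DataFrame(cols, index=ids)
    truth = pd.DataFrame(
        {
            "id": [ids[i] for i in de_idx],
            "log2fc": lfc,
            "direction": np.where(lfc > 0, "up", "down"),
            "kind": "piRNA",
        }
    ).sort_values("id", ignore_index=True)
    return counts, truth


def simulate_target_sequences(
    n_pirnas: int = 20,
    n_targets: int = 20,
    planted_pairs: int = 5,
    mutation_rate: float = 0.0,
    seed: int = 0,
    pirna_len: int = 30,
    target_len: int = 200,
) -> tuple[dict[str, str], dict[str, str], SimTruth]:
    """Random piRNA and target sequences; planted targets embed the
    (optionally mutated) reverse complement of their piRNA."""
    if planted_pairs > min(n_pirnas, n_targets):
        raise ValueError("planted_pairs must be <= min(n_pirnas, n_targets)")
    rng = np.random.default_rng(seed)
    pirnas = {
        f"sim_piRNA_{i + 1}": _random_seq(rng, pirna_len) for i in range(n_pirnas)
    }
    targets = {
        f"target_{j + 1}": _random_seq(rng, target_len) for j in range(n_targets)
    }
    truth = SimTruth(
        seed=seed,
        params={
            "n_pirnas": n_pirnas,
            "n_targets": n_targets,
            "mutation_rate": mutation_rate,
            "pirna_len": pirna_len,
            "target_len": target_len,
        },
    )
    p_ids = rng.permutation(sorted(pirnas))[:planted_pairs]
    t_ids = rng.permutation(sorted(targets))[:planted_pairs]
    for pid, tid in zip(p_ids, t_ids):
        site = list(reverse_complement(pirnas[pid]))
        n_mut = 0
        for i in range(len(site)):
            if rng.random() < mutation_rate:
                site[i] = str(rng.choice(_BASES[_BASES != site[i]]))
                n_mut += 1
        offset = int(rng.integers(0, target_len - pirna_len + 1))
        t = targets[tid]
        targets[tid] = t[:offset] + "".join(site) + t[offset + len(site):]
        truth.target_pairs.append(
            {
                "pirna_id": str(pid),
                "target_id": str(tid),
                "offset": offset,
                "n_mutations": n_mut,
            }
        )
    return pirnas, targets, truth
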