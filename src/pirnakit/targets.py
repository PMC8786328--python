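"""piRNA:target duplex prediction.

A local complementarity aligner (Smith-Waterman with affine gaps and G:U
wobble awareness) scores the reverse-complemented piRNA against candidate
target sequences, with the piRNA 5'-end positions 2-8 up-weighted. A
nearest-neighbour stacking model estimates duplex free energy. Candidate
pairs pass when score >= score_min and energy <= energy_max (defaults
170 and -20 kcal/mol).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .io_model import normalize_sequence

__all__ = [
    "ScoringParams",
    "DuplexAlignment",
    "duplex_align",
    "duplex_energy",
    "predict_targets",
    "reverse_complement",
    "dinucleotide_shuffle",
    "load_stack_table",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# query/target wobble pairs: piRNA G with target U -> query C vs target T,
# piRNA U with target G -> query A vs target G
_WOBBLE = {("C", "T"), ("A", "G")}

MATCH, WOBBLE, MISMATCH, GAP = "|", ":", ".", "-"


def reverse_complement(seq: str) -> str:
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]


def load_stack_table() -> dict[str, float]:
    """Pinned Watson-Crick nearest-neighbour stacking table (kcal/mol)."""
    text = (
        resources.files("pirnakit").joinpath("data/nn_stack.json").read_text()
    )
    return json.loads(text)["stack"]


@dataclass(frozen=True)
class ScoringParams:
    """Alignment and energy-model parameters (score units are internal to
    this scorer, not comparable bit-for-bit with external aligners)."""

    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_start: int = 2  # 1-based piRNA position, inclusive
    seed_end: int = 8
    seed_scale: float = 2.0
    score_min: float = 170.0
    energy_max: float = -20.0
    loop_penalty: float = 4.0


DEFAULT_PARAMS = ScoringParams()


@dataclass
class DuplexAlignment:
    """A piRNA:target duplex with its score, energy and pairing trace."""

    pirna_id: str
    target_id: str
    score: float
    energy: float
    target_start: int
    target_end: int
    aligned_query: str  # reverse-complemented piRNA segment, 5'->3'
    aligned_target: str
    pairing: str  # one symbol per column: | match, : wobble, . mismatch, - gap

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if len(self.pairing) != len(self.aligned_query) or len(
            self.pairing
        ) != len(self.aligned_target):
            raise ValueError("pairing string length must equal alignment length")

    @property
    def window(self) -> tuple[int, int]:
        return (self.target_start, self.target_end)

    @property
    def n_paired(self) -> int:
        return sum(c in (MATCH, WOBBLE) for c in self.pairing)


def _column_score(qc: str, tc: str, params: ScoringParams) -> tuple[float, str]:
    if qc == tc and qc in "ACGT":
        return params.match, MATCH
    if (qc, tc) in _WOBBLE:
        return params.wobble, WOBBLE
    return params.mismatch, MISMATCH


def seed_weights(pirna_len: int, params: ScoringParams) -> np.ndarray:
    """Per-query-position weight: query index j pairs piRNA position
    ``pirna_len - j`` (1-based from the piRNA 5' end)."""
    w = np.ones(pirna_len)
    for j in range(pirna_len):
        if params.seed_start <= pirna_len - j <= params.seed_end:
            w[j] = params.seed_scale
    return w


def _align_core(
    query: str, target: str, weights: np.ndarray, params: ScoringParams
) -> tuple[float, int, int, str, str, str]:
    """Affine-gap local alignment of query vs target.

    Returns (score, target_start, target_end, aligned_query,
    aligned_target, pairing). Ties on score prefer the smaller target
    start, then the shorter alignment.
    """
    nq, nt = len(query), len(target)
    NEG = -1e30
    H = np.zeros((nt + 1, nq + 1))
    E = np.full((nt + 1, nq + 1), NEG)  # gap in query (consumes target)
    F = np.full((nt + 1, nq + 1), NEG)  # gap in target (consumes query)
    sub = np.zeros((nt + 1, nq + 1))
    kind = np.empty((nt + 1, nq + 1), dtype="U1")
    for i in range(1, nt + 1):
        for j in range(1, nq + 1):
            s, k = _column_score(query[j - 1], target[i - 1], params)
            sub[i, j] = s * weights[j - 1]
            kind[i, j] = k
    for i in range(1, nt + 1):
        for j in range(1, nq + 1):
            E[i, j] = max(H[i - 1, j] + params.gap_open, E[i - 1, j] + params.gap_extend)
            F[i, j] = max(H[i, j - 1] + params.gap_open, F[i, j - 1] + params.gap_extend)
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub[i, j], E[i, j], F[i, j])

    best = float(H.max())
    if best <= 0:
        return 0.0, 0, 0, "", "", ""

    candidates = []
    for i, j in zip(*np.nonzero(H == best)):
        aln = _traceback(int(i), int(j), H, E, F, sub, kind, query, target, params)
        tstart, aq, at, pairing = aln
        candidates.append((tstart, len(pairing), int(i), aq, at, pairing))
    tstart, _, tend, aq, at, pairing = min(candidates)[:6]
    return best, tstart, tend, aq, at, pairing


def _traceback(i, j, H, E, F, sub, kind, query, target, params):
    aq, at, pairing = [], [], []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + sub[i, j]:
                aq.append(query[j - 1])
                at.append(target[i - 1])
                pairing.append(kind[i, j])
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            aq.append(GAP)
            at.append(target[i - 1])
            pairing.append(GAP)
            if E[i, j] == H[i - 1, j] + params.gap_open:
                state = "H"
            i -= 1
        else:  # F
            aq.append(query[j - 1])
            at.append(GAP)
            pairing.append(GAP)
            if F[i, j] == H[i, j - 1] + params.gap_open:
                state = "H"
            j -= 1
    return i, "".join(reversed(aq)), "".join(reversed(at)), "".join(reversed(pairing))


def duplex_align(
    pirna: str,
    target: str,
    params: ScoringParams = DEFAULT_PARAMS,
    pirna_id: str = ".",
    target_id: str = ".",
    enforce_lengths: bool = True,
) -> DuplexAlignment:
    """Best local duplex between a piRNA and a target sequence.

    The reverse complement of the piRNA is aligned against the target so
    that matches correspond to Watson-Crick pairing; piRNA positions 2-8
    are scaled by ``seed_scale``.
    """
    p = normalize_sequence(pirna)
    t = normalize_sequence(target)
    if enforce_lengths:
        if len(p) < 16:
            raise ValueError(f"piRNA shorter than 16 nt ({len(p)})")
        if len(t) < len(p):
            raise ValueError("target shorter than piRNA")
    query = reverse_complement(p)
    weights = seed_weights(len(query), params)
    score, tstart, tend, aq, at, pairing = _align_core(query, t, weights, params)
    aln = DuplexAlignment(
        pirna_id=pirna_id,
        target_id=target_id,
        score=score,
        energy=0.0,
        target_start=tstart,
        target_end=tend,
        aligned_query=aq,
        aligned_target=at,
        pairing=pairing,
    )
    aln.energy = duplex_energy(aln, params)
    return aln


def duplex_energy(
    alignment: DuplexAlignment, params: ScoringParams = DEFAULT_PARAMS
) -> float:
    """Nearest-neighbour free-energy estimate for an alignment, kcal/mol.

    Consecutive Watson-Crick paired columns contribute stacking terms from
    the pinned table (keyed by the target-strand dinucleotide); each
    interior run of unpaired columns (mismatch or gap) adds a loop/bulge
    penalty. Wobble columns count as paired but contribute no stacking.
    """
    table = load_stack_table()
    paired = [c in (MATCH, WOBBLE) for c in alignment.pairing]
    if not any(paired):
        warnings.warn("alignment has no paired positions; energy = 0",
                      stacklevel=2)
        return 0.0
    first = paired.index(True)
    last = len(paired) - 1 - paired[::-1].index(True)
    energy = 0.0
    in_loop = False
    for c in range(first, last + 1):
        if not paired[c]:
            if not in_loop:
                energy += params.loop_penalty
                in_loop = True
            continue
        in_loop = False
        if (
            c + 1 <= last
            and alignment.pairing[c] == MATCH
            and alignment.pairing[c + 1] == MATCH
        ):
            key = alignment.aligned_target[c] + alignment.aligned_target[c + 1]
            energy += table.get(key, 0.0)
    return energy


def predict_targets(
    candidate_pairs: Sequence[tuple[str, str]],
    pirna_seqs: Mapping[str, str],
    target_seqs: Mapping[str, str],
    score_min: float | None = None,
    energy_max: float | None = None,
    params: ScoringParams = DEFAULT_PARAMS,
) -> tuple[list[DuplexAlignment], list[dict]]:
    """Align every candidate (piRNA, target) pair and keep those passing
    both gates. Missing sequences yield per-pair error records; the run
    continues. Hits are sorted by descending score, then ids.
    """
    score_min = params.score_min if score_min is None else score_min
    energy_max = params.energy_max if energy_max is None else energy_max
    hits: list[DuplexAlignment] = []
    errors: list[dict] = []
    for pid, tid in candidate_pairs:
        if pid not in pirna_seqs or tid not in target_seqs:
            errors.append(
                {
                    "pirna_id": pid,
                    "target_id": tid,
                    "error": "missing sequence",
                }
            )
            continue
        try:
            aln = duplex_align(
                pirna_seqs[pid], target_seqs[tid], params, pid, tid
            )
        except ValueError as exc:
            errors.append(
                {"pirna_id": pid, "target_id": tid, "error": str(exc)}
            )
            continue
        if aln.score >= score_min and aln.energy <= energy_max:
            hits.append(aln)
    hits.sort(key=lambda a: (-a.score, a.pirna_id, a.target_id))
    return hits, errors


def dinucleotide_shuffle(
    seq: str, rng: np.random.Generator, max_tries: int = 100
) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Edge lists of the dinucleotide walk are permuted and re-walked until
    an Eulerian traversal consumes every edge (retry on failure).
    """
    s = normalize_sequence(seq)
    if len(s) < 3:
        return s
    for _ in range(max_tries):
        edges: dict[str, list[str]] = {}
        for a, b in zip(s, s[1:]):
            edges.setdefault(a, []).append(b)
        for v in edges:
            rng.shuffle(edges[v])
        walk = [s[0]]
        node = s[0]
        total = len(s) - 1
        for _ in range(total):
            nxt = edges.get(node)
            if not nxt:
                break
            node = nxt.pop()
            walk.append(node)
        if len(walk) == len(s):
            return "".join(walk)
    return s  # degenerate composition; original is the only arrangement
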