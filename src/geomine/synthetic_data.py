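"""Synthetic inputs with known ground truth for every pipeline stage.

No public accessions underlie the mined enzyme set, so all pipeline inputs
can be regenerated here: a simulated protein family with a tunable pairwise
identity distribution and a planted low-energy "functional" clade, docking
score tables, noisy Michaelis-Menten / substrate-inhibition velocity curves,
design-simulation sequence sets, and replicate titer tables with a limit of
quantitation.  Every generator is a pure function of its spec plus one
integer seed and returns truth objects sufficient for downstream
parameter-recovery tests.

The family generator evolves i.i.d. sites along a binary guide tree: each
site accumulates a Poisson(rate x branch length) number of substitution
events, each replacing the residue uniformly among the other 19.  Expected
pairwise identity between leaves separated by total path length T is then
1/20 + (19/20) exp(-20 T / 19); the defaults (unit root-to-leaf depth,
rate 1.0) put the alignment-identity mode near 20% — the diversity regime of
a deeply diverged single-fold family, where measured identity is dominated
by the twilight-zone alignment floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .candidate_selection import GeoCandidate
from .kinetics_analysis import KineticDataset
from .product_profile import DEFAULT_LOQ_MG_L, TiterTable
from .sequence_mining import AMINO_ACIDS, SequenceRecord

__all__ = [
    "FamilySimSpec",
    "ScoreSimSpec",
    "KineticsSimSpec",
    "simulate_family",
    "simulate_scores",
    "simulate_kinetics",
    "simulate_design_set",
    "simulate_titers",
]

_AA = np.array(list(AMINO_ACIDS))


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class FamilySimSpec:
    """Specification of a simulated protein family.

    ``tree_depth`` is the root-to-leaf depth of the guide tree in branch
    length units; ``functional_clade_fraction`` picks the subtree closest in
    size to that fraction of the leaves as the planted functional clade;
    ``eukaryote_fraction`` labels that share of leaves as eukaryotic so the
    taxonomy filter has something to remove.
    """

    n_sequences: int = 120
    root_length: int = 200
    substitution_rate: float = 1.0
    tree_shape: Literal["balanced", "coalescent"] = "coalescent"
    functional_clade_fraction: float = 0.15
    seed: int = 0
    tree_depth: float = 1.0
    eukaryote_fraction: float = 0.1

    def __post_init__(self) -> None:
        _require(self.n_sequences >= 2, "n_sequences", "must be >= 2")
        _require(self.root_length >= 1, "root_length", "must be >= 1")
        _require(self.substitution_rate >= 0, "substitution_rate", "must be >= 0")
        _require(self.tree_shape in ("balanced", "coalescent"), "tree_shape",
                 "must be 'balanced' or 'coalescent'")
        _require(0.0 <= self.functional_clade_fraction <= 1.0,
                 "functional_clade_fraction", "must lie in [0, 1]")
        _require(self.tree_depth > 0, "tree_depth", "must be > 0")
        _require(0.0 <= self.eukaryote_fraction <= 1.0, "eukaryote_fraction",
                 "must lie in [0, 1]")


@dataclass(frozen=True)
class ScoreSimSpec:
    """Specification of simulated docking scores over a family.

    The functional clade draws interface energies around
    ``clade_energy_mean``, everything else around ``background_energy_mean``
    (additive Gaussian noise, Rosetta-energy-unit-like scale); the clade must
    be lower-energy by construction.
    """

    clade_energy_mean: float = -12.0
    background_energy_mean: float = -2.0
    noise_sd: float = 1.0
    tm_score_range: tuple[float, float] = (0.55, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.clade_energy_mean < self.background_energy_mean,
                 "clade_energy_mean", "must be below background_energy_mean")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        lo, hi = self.tm_score_range
        _require(0.0 <= lo <= hi <= 1.0, "tm_score_range",
                 "must be an interval within [0, 1]")


@dataclass(frozen=True)
class KineticsSimSpec:
    """Specification of a simulated initial-velocity curve.

    Defaults emulate a typical assay: substrate grid spanning 0.005-10 mM,
    5% multiplicative velocity noise, micromolar-scale enzyme.  A missing
    ``true_Ki`` selects the pure Michaelis-Menten generator.
    """

    true_kcat: float = 10.1  # s^-1
    true_KM: float = 0.58  # mM
    true_Ki: float | None = None  # mM
    enzyme_conc: float = 1e-6  # M
    substrate_grid: tuple[float, ...] = (0.005, 0.015, 0.05, 0.15, 0.5, 1.5, 3.0, 5.0, 7.5, 10.0)
    noise_sd: float = 0.05  # fraction of the velocity
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.true_kcat > 0, "true_kcat", "must be > 0")
        _require(self.true_KM > 0, "true_KM", "must be > 0")
        if self.true_Ki is not None:
            _require(self.true_Ki > 0, "true_Ki", "must be > 0")
        _require(self.enzyme_conc > 0, "enzyme_conc", "must be > 0")
        _require(len(self.substrate_grid) >= 5, "substrate_grid",
                 "needs at least 5 concentrations")
        _require(all(s > 0 for s in self.substrate_grid), "substrate_grid",
                 "all concentrations must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


# ---------------------------------------------------------------------------
# guide trees


@dataclass
class _Node:
    children: list["tuple[_Node, float]"] = field(default_factory=list)
    leaf_index: int | None = None

    def leaves(self) -> list[int]:
        if self.leaf_index is not None:
            return [self.leaf_index]
        out: list[int] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


def _balanced_tree(n: int, depth: float) -> _Node:
    """Binary split of the leaf index range, equal branch lengths per level."""
    levels = max(int(np.ceil(np.log2(n))), 1)
    step = depth / levels

    def build(indices: list[int], remaining: int) -> _Node:
        if len(indices) == 1:
            node = _Node(leaf_index=indices[0])
            # pad so every leaf sits at exactly `depth` from the root
            if remaining > 0:
                for _ in range(remaining):
                    node = _Node(children=[(node, step)])
            return node
        half = (len(indices) + 1) // 2
        left = build(indices[:half], remaining - 1)
        right = build(indices[half:], remaining - 1)
        return _Node(children=[(left, step), (right, step)])

    return build(list(range(n)), levels)


def _coalescent_tree(n: int, depth: float, rng: np.random.Generator) -> _Node:
    """Random sequential pair-joining with node heights scaled to ``depth``."""
    heights = {i: 0.0 for i in range(n)}
    nodes: dict[int, _Node] = {i: _Node(leaf_index=i) for i in range(n)}
    active = list(range(n))
    next_id = n
    height = 0.0
    increments = rng.exponential(scale=1.0, size=n - 1)
    increments = increments / increments.sum() * depth
    for step in range(n - 1):
        height += increments[step]
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent = _Node(children=[(nodes[a], height - heights[a]),
                                 (nodes[b], height - heights[b])])
        nodes[next_id] = parent
        heights[next_id] = height
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return nodes[next_id - 1]


def _pick_clade(root: _Node, n: int, fraction: float) -> set[int]:
    if fraction <= 0:
        return set()
    target = fraction * n
    best: tuple[float, list[int]] | None = None
    stack = [root]
    while stack:
        node = stack.pop()
        if node.leaf_index is not None:
            leaves = [node.leaf_index]
        else:
            leaves = node.leaves()
            for child, _ in node.children:
                stack.append(child)
        if len(leaves) < n:  # the root itself is not a clade choice
            score = abs(len(leaves) - target)
            if best is None or score < best[0]:
                best = (score, leaves)
    return set(best[1]) if best else set()


def _evolve(seq: np.ndarray, rate: float, branch_length: float,
            rng: np.random.Generator) -> np.ndarray:
    child = seq.copy()
    n_events = rng.poisson(rate * branch_length, size=child.size)
    for site in np.nonzero(n_events)[0]:
        for _ in range(n_events[site]):
            current = child[site]
            choices = [a for a in AMINO_ACIDS if a != current]
            child[site] = choices[rng.integers(0, 19)]
    return child


def simulate_family(spec: FamilySimSpec) -> tuple[list[SequenceRecord], set[str]]:
    """Simulate a family; returns records and the ids of the functional clade.

    With ``substitution_rate == 0`` all sequences equal the root sequence.
    Identical specs (including the seed) give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sequences
    if spec.tree_shape == "balanced":
        root = _balanced_tree(n, spec.tree_depth)
    else:
        root = _coalescent_tree(n, spec.tree_depth, rng)
    clade_indices = _pick_clade(root, n, spec.functional_clade_fraction)

    root_seq = _AA[rng.integers(0, 20, size=spec.root_length)]
    sequences: dict[int, np.ndarray] = {}

    def descend(node: _Node, seq: np.ndarray) -> None:
        if node.leaf_index is not None:
            sequences[node.leaf_index] = seq
            return
        for child, bl in node.children:
            descend(child, _evolve(seq, spec.substitution_rate, bl, rng))

    descend(root, root_seq)

    is_euk = rng.random(n) < spec.eukaryote_fraction
    width = len(str(n - 1))
    records = []
    clade_ids: set[str] = set()
    for i in range(n):
        rid = f"seq{i:0{width}d}"
        domain = "Eukaryota" if is_euk[i] else "Bacteria"
        in_clade = i in clade_indices
        records.append(
            SequenceRecord(
                id=rid,
                sequence="".join(sequences[i]),
                taxonomy_domain=domain,
                description=f"tax={domain} clade={int(in_clade)}",
            )
        )
        if in_clade:
            clade_ids.add(rid)
    return records, clade_ids


def simulate_scores(
    records: Sequence[SequenceRecord],
    clade_ids: set[str],
    spec: ScoreSimSpec,
) -> list[GeoCandidate]:
    """Attach TM-scores and interface energies; the clade is lower-energy.

    With ``noise_sd == 0`` clade members score exactly
    ``clade_energy_mean`` and the energy ranking puts the clade first.
    """
    if not records:
        raise ValueError("records must be non-empty")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.tm_score_range
    out = []
    for rec in records:
        mean = spec.clade_energy_mean if rec.id in clade_ids else spec.background_energy_mean
        energy = mean + rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else mean
        tm = float(rng.uniform(lo, hi))
        out.append(GeoCandidate(record=rec, tm_score=tm, interface_energy=float(energy)))
    return out


def simulate_kinetics(spec: KineticsSimSpec) -> tuple[KineticDataset, dict]:
    """Noisy initial-velocity curve plus the generating truth.

    v = kcat E0 S / (KM + S [+ S^2/Ki]) times (1 + Gaussian noise).
    """
    rng = np.random.default_rng(spec.seed)
    s = np.asarray(spec.substrate_grid, dtype=float)
    denom = spec.true_KM + s
    if spec.true_Ki is not None:
        denom = denom + s**2 / spec.true_Ki
    v_true = spec.true_kcat * spec.enzyme_conc * s / denom
    if spec.noise_sd > 0:
        v = v_true * (1.0 + rng.normal(0.0, spec.noise_sd, size=s.size))
    else:
        v = v_true.copy()
    data = KineticDataset(
        substrate="synthetic",
        concentrations_mM=s,
        velocities_M_per_s=v,
        enzyme_conc_M=spec.enzyme_conc,
    )
    truth = {
        "kcat": spec.true_kcat,
        "KM_mM": spec.true_KM,
        "Ki_mM": spec.true_Ki,
        "enzyme_conc_M": spec.enzyme_conc,
        "velocities_noiseless": v_true,
    }
    return data, truth


def simulate_design_set(
    n_designs: int,
    positions: Sequence[int],
    native: str,
    allowed_alphabet: Sequence[str],
    seed: int = 0,
) -> list[str]:
    """Design sequences differing from native only at the stated positions.

    At each design position every design draws uniformly from the allowed
    alphabet plus the native residue (a position may stay native).
    """
    if n_designs < 1:
        raise ValueError("n_designs must be >= 1")
    positions = list(positions)
    if len(set(positions)) != len(positions):
        raise ValueError("positions must be distinct")
    if not allowed_alphabet:
        raise ValueError("allowed_alphabet must be non-empty")
    for p in positions:
        if not (1 <= p <= len(native)):
            raise ValueError(f"position {p} outside native length {len(native)}")
    rng = np.random.default_rng(seed)
    designs = []
    for _ in range(n_designs):
        seq = list(native)
        for p in positions:
            choices = sorted(set(allowed_alphabet) | {native[p - 1]})
            seq[p - 1] = choices[rng.integers(0, len(choices))]
        designs.append("".join(seq))
    return designs


def simulate_titers(
    true_means: dict[str, float],
    replicate_sd: float,
    n_reps: int = 3,
    loq: float = DEFAULT_LOQ_MG_L,
    seed: int = 0,
    strain: str = "synthetic",
) -> tuple[TiterTable, dict[str, float]]:
    """Replicate titer draws (additive Gaussian noise, clipped at zero).

    Alcohols whose replicates dip below the LOQ are flagged unquantified by
    the returned :class:`TiterTable`.  Returns the table and the true means.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if replicate_sd < 0:
        raise ValueError("replicate_sd must be >= 0")
    rng = np.random.default_rng(seed)
    replicates = {}
    for alcohol, mean in true_means.items():
        draws = mean + rng.normal(0.0, replicate_sd, size=n_reps) if replicate_sd > 0 \
            else np.full(n_reps, float(mean))
        replicates[alcohol] = tuple(np.clip(draws, 0.0, None))
    table = TiterTable(strain=strain, replicates=replicates, loq=loq)
    return table, dict(true_means)
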