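"""Synthetic library synthesis, host passage and read emission.

The simulator embodies the two bias mechanisms that dominate real NNK
phage-display libraries:

1. **Unequal phosphoramidite incorporation.**  The base drawn at each random
   position follows an effective probability proportional to stock molar
   ratio x incorporation efficiency, so a G-efficient chemistry skews the
   whole composition even from an equimolar stock.

2. **Amber-driven growth advantage.**  In a type-88 vector, abortive
   termination of the recombinant coat protein at a UAG codon yields a
   phage with wild-type phenotype that escapes the display burden.  In
   supE44- hosts UAG clones therefore out-replicate displaying clones; in
   supE44+ hosts readthrough (as Gln) re-imposes the burden in proportion
   to the suppression efficiency.

Growth is modelled as deterministic exponential weight update (expectation
dynamics, no demographic noise), which makes every downstream test exact.
All randomness flows from one integer seed: identical seed, byte-identical
FASTQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, TextIO, Union

import numpy as np

from .design import BASES, K_BASES, LibraryDesign
from .peptides import NO_STOP, OTHER_STOP, UAG_ONLY, classify_stops

DEFECT_NONE = "none"
DEFECT_INDEL = "indel"
DEFECT_BARCODE = "wrong_barcode"
DEFECT_NON_NNK = "non_nnk_third_base"
DEFECT_TYPES = (DEFECT_INDEL, DEFECT_BARCODE, DEFECT_NON_NNK)


def _as_probs(ratio: dict[str, float], eff: dict[str, float], bases: str) -> np.ndarray:
    w = np.array([ratio[b] * eff[b] for b in bases], dtype=float)
    return w / w.sum()


@dataclass(frozen=True)
class SynthesisModel:
    """Stock molar ratios and per-base incorporation efficiencies.

    Effective incorporation probability at an N position for base b is
    ``stock_ratio_n[b] * efficiency[b]`` normalised over ACGT; K positions
    are analogous over GT.  Efficiencies are dimensionless, G-relative.
    """

    stock_ratio_n: dict[str, float] = field(
        default_factory=lambda: {b: 1.0 for b in BASES}
    )
    stock_ratio_k: dict[str, float] = field(
        default_factory=lambda: {b: 1.0 for b in K_BASES}
    )
    efficiency: dict[str, float] = field(
        default_factory=lambda: {b: 1.0 for b in BASES}
    )

    def __post_init__(self) -> None:
        for name, d, keys in (
            ("stock_ratio_n", self.stock_ratio_n, BASES),
            ("stock_ratio_k", self.stock_ratio_k, K_BASES),
            ("efficiency", self.efficiency, BASES),
        ):
            missing = set(keys) - set(d)
            if missing:
                raise ValueError(f"{name} missing bases {sorted(missing)}")
            if any(d[k] <= 0 for k in keys):
                raise ValueError(f"{name} entries must be > 0")

    def n_probs(self) -> np.ndarray:
        """Effective base probabilities (A,C,G,T order) at an N position."""
        return _as_probs(self.stock_ratio_n, self.efficiency, BASES)

    def k_probs(self) -> np.ndarray:
        """Effective base probabilities (G,T order) at a K position."""
        return _as_probs(self.stock_ratio_k, self.efficiency, K_BASES)

    @classmethod
    def equimolar(cls) -> "SynthesisModel":
        return cls()

    @classmethod
    def g_biased(cls) -> "SynthesisModel":
        """Equimolar stock with the efficiency skew typical of uncalibrated
        synthesis (G fastest; the skew that the calibrated stock
        G:1.0, A:1.5, T:1.5, C:1.6 exactly compensates)."""
        return cls(efficiency={"G": 1.0, "A": 2 / 3, "T": 2 / 3, "C": 0.625})


@dataclass(frozen=True)
class HostModel:
    """Host-strain genetics and display burden.

    suppression_efficiency is the probability an amber codon is read through
    as Gln (0 in supE44- hosts).  display_burden is the per-generation
    fitness cost of assembling the recombinant coat protein.  Clone fitness:

    * insert with >=1 TGA/TAA: 1 (abortive termination, wild-type phenotype)
    * insert with >=1 UAG (no other stop): 1 - suppression_efficiency * burden
    * stop-free displaying insert: 1 - burden
    """

    supE44: bool
    suppression_efficiency: float = 0.0
    display_burden: float = 0.0
    generations: float = 1.0
    opal_suppression_efficiency: float = 0.0

    def __post_init__(self) -> None:
        if not self.supE44 and self.suppression_efficiency != 0.0:
            raise ValueError("suppression_efficiency must be 0 in supE44- hosts")
        for name in ("suppression_efficiency", "display_burden",
                     "opal_suppression_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")

    def fitness(self, stop_class: str) -> float:
        if stop_class == OTHER_STOP:
            return 1.0 - self.opal_suppression_efficiency * self.display_burden
        if stop_class == UAG_ONLY:
            return 1.0 - self.suppression_efficiency * self.display_burden
        return 1.0 - self.display_burden


@dataclass
class SimulatedPopulation:
    """Clone inserts with abundance weights plus provenance."""

    inserts: list[str]
    weights: np.ndarray
    design: LibraryDesign
    synthesis: SynthesisModel
    host: Optional[HostModel] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.inserts) != len(self.weights):
            raise ValueError("inserts and weights length mismatch")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def uag_fraction(self) -> float:
        """Weight fraction of clones whose insert carries >=1 amber codon."""
        mask = np.array(
            [classify_stops(s) == UAG_ONLY for s in self.inserts], dtype=bool
        )
        return float(self.weights[mask].sum() / self.total_weight)

    def stop_class_fractions(self) -> dict[str, float]:
        out = {NO_STOP: 0.0, UAG_ONLY: 0.0, OTHER_STOP: 0.0}
        for insert, w in zip(self.inserts, self.weights):
            out[classify_stops(insert)] += w
        total = self.total_weight
        return {k: v / total for k, v in out.items()}


def sample_insert_matrix(
    design: LibraryDesign, model: SynthesisModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n inserts as an (n, insert_length) array of single characters."""
    k = design.n_random_codons
    pn, pk = model.n_probs(), model.k_probs()
    n_bases = np.array(list(BASES))
    k_bases = np.array(list(K_BASES))
    codons = np.empty((n, k, 3), dtype="<U1")
    codons[:, :, 0] = n_bases[rng.choice(4, size=(n, k), p=pn)]
    codons[:, :, 1] = n_bases[rng.choice(4, size=(n, k), p=pn)]
    codons[:, :, 2] = k_bases[rng.choice(2, size=(n, k), p=pk)]
    random = codons.reshape(n, 3 * k)
    if not design.constrained:
        return random
    cys = np.array(list(design.cys_codon))
    out = np.empty((n, design.insert_length), dtype="<U1")
    out[:, :3] = cys
    out[:, 3:-3] = random
    out[:, -3:] = cys
    return out


def sample_nnk_insert(
    design: LibraryDesign, model: SynthesisModel, rng: np.random.Generator
) -> str:
    """Draw one insert; each random position independent per the model."""
    return "".join(sample_insert_matrix(design, model, 1, rng)[0])


def build_naive_pool(
    design: LibraryDesign,
    model: SynthesisModel,
    n_clones: int,
    rng: np.random.Generator,
    seed: Optional[int] = None,
) -> SimulatedPopulation:
    """n_clones independent inserts, each with weight 1 (pre-growth pool)."""
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    mat = sample_insert_matrix(design, model, n_clones, rng)
    inserts = ["".join(row) for row in mat]
    return SimulatedPopulation(
        inserts=inserts,
        weights=np.ones(n_clones),
        design=design,
        synthesis=model,
        seed=seed,
    )


def passage(pop: SimulatedPopulation, host: HostModel) -> SimulatedPopulation:
    """Deterministic growth: each clone's weight scaled by fitness^generations.

    Clone identity is conserved (no sequences created or destroyed); the
    update is order-independent.  With suppression_efficiency = 1 or
    display_burden = 0 all clones share one fitness and relative abundances
    are unchanged.
    """
    if host.generations < 0:
        raise ValueError("generations must be >= 0")
    factors = np.array(
        [host.fitness(classify_stops(s)) ** host.generations for s in pop.inserts]
    )
    return SimulatedPopulation(
        inserts=list(pop.inserts),
        weights=pop.weights * factors,
        design=pop.design,
        synthesis=pop.synthesis,
        host=host,
        seed=pop.seed,
    )


def _apply_defect(
    read: list[str], defect: str, design: LibraryDesign, rng: np.random.Generator
) -> list[str]:
    up = len(design.upstream_flank)
    ins_len = design.insert_length
    if defect == DEFECT_INDEL:
        pos = up + int(rng.integers(ins_len))
        if rng.random() < 0.5:
            base = BASES[int(rng.integers(4))]
            read = read[:pos] + [base] + read[pos:]
        else:
            read = read[:pos] + read[pos + 1 :]
    elif defect == DEFECT_BARCODE:
        pos = design.barcode_offset + int(rng.integers(len(design.barcode)))
        old = read[pos]
        choices = [b for b in BASES if b != old]
        read[pos] = choices[int(rng.integers(3))]
    elif defect == DEFECT_NON_NNK:
        # third base of a random codon forced to A or C
        start = up + (3 if design.constrained else 0)
        codon = int(rng.integers(design.n_random_codons))
        read[start + 3 * codon + 2] = "AC"[int(rng.integers(2))]
    else:  # pragma: no cover
        raise ValueError(f"unknown defect {defect!r}")
    return read


def emit_reads(
    pop: SimulatedPopulation,
    design: LibraryDesign,
    n_reads: int,
    error_rate: float = 0.0,
    aberrant_fraction: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    quality: int = 40,
) -> tuple[list[tuple[str, str]], list[tuple[str, str, str]]]:
    """Sample reads from the population and return (records, truth).

    records: (read_id, sequence) pairs; truth: (read_id, clone insert,
    defect type).  Reads are drawn with probability proportional to clone
    weight; the full amplicon layout is emitted.  Substitution errors hit
    every base independently at ``error_rate``; an ``aberrant_fraction`` of
    reads additionally carry one deliberate defect drawn uniformly from
    {insert indel, barcode substitution, non-NNK third base}.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if rng is None:
        rng = np.random.default_rng(pop.seed)
    total = pop.total_weight
    if n_reads > 0 and total <= 0:
        raise ValueError("population has zero total weight")
    defect_pool = list(DEFECT_TYPES)
    if not design.barcode:
        defect_pool.remove(DEFECT_BARCODE)
    records: list[tuple[str, str]] = []
    truth: list[tuple[str, str, str]] = []
    if n_reads == 0:
        return records, truth
    probs = pop.weights / total
    clone_idx = rng.choice(len(pop.inserts), size=n_reads, p=probs)
    aberrant = rng.random(n_reads) < aberrant_fraction
    width = len(str(max(n_reads, 1)))
    for i in range(n_reads):
        insert = pop.inserts[int(clone_idx[i])]
        read = list(design.upstream_flank + insert + design.downstream_flank)
        defect = DEFECT_NONE
        if aberrant[i]:
            defect = defect_pool[int(rng.integers(len(defect_pool)))]
            read = _apply_defect(read, defect, design, rng)
        if error_rate > 0:
            hits = np.nonzero(rng.random(len(read)) < error_rate)[0]
            for pos in hits:
                old = read[pos]
                choices = [b for b in BASES if b != old]
                read[pos] = choices[int(rng.integers(3))]
        rid = f"read_{i:0{width}d}"
        records.append((rid, "".join(read)))
        truth.append((rid, insert, defect))
    return records, truth


def write_fastq(
    records: list[tuple[str, str]],
    path: Union[str, Path, TextIO],
    quality: int = 40,
) -> None:
    """Write 4-line FASTQ (Phred+33, constant quality). Deterministic bytes."""
    qchar = chr(33 + quality)
    own = isinstance(path, (str, Path))
    fh = open(path, "w") if own else path
    try:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qchar * len(seq)}\n")
    finally:
        if own:
            fh.close()


def write_truth(truth: list[tuple[str, str, str]], path: Union[str, Path]) -> None:
    """Ground-truth TSV: read_id, clone insert, injected defect type."""
    with open(path, "w") as fh:
        fh.write("read_id\tinsert\tdefect\n")
        for rid, insert, defect in truth:
            fh.write(f"{rid}\t{insert}\t{defect}\n")
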