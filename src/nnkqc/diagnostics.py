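"""Randomness statistics for NNK libraries and their analytic expectations.

A perfectly random NNK library has per-position base fractions
25/25/25/25 at N slots and 50/50 (G/T) at the K slot, a degeneracy-
normalized amino-acid distribution flat at 1/21 (20 residues plus the extra
Gln contributed by amber readthrough), and a probability
``1 - (31/32)^n`` that an n-codon insert carries at least one amber codon
(about 27% at n = 10).  Deviations from these expectations are what this
module quantifies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    AMBER,
    BASES,
    K_BASES,
    LibraryDesign,
    NNK_CODONS,
    nnk_nucleotide_complexity,
    theoretical_complexity,
    translate_codon,
)
from .peptides import PeptideTable, tabulate
from .preprocess import FilterReport, InsertTable

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class CompositionProfile:
    """Read-weighted base fractions at every random position.

    ``fractions`` is indexed by 0-based random-region position with columns
    A,C,G,T; ``positions`` carries codon_index and slot (1-3) metadata and
    the observation count per position.
    """

    fractions: pd.DataFrame
    positions: pd.DataFrame

    @property
    def n_positions(self) -> int:
        return len(self.fractions)


def nucleotide_composition(inserts: InsertTable) -> CompositionProfile:
    """Per-position base fractions over the random region, read-weighted."""
    if not inserts.counts:
        raise ValueError("empty insert table")
    design = inserts.design
    n_pos = 3 * design.n_random_codons
    seqs = [design.random_region(s) for s in inserts.counts]
    weights = np.array(list(inserts.counts.values()), dtype=float)
    mat = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), n_pos)
    counts = np.zeros((n_pos, 4))
    for bi, base in enumerate(BASES):
        counts[:, bi] = ((mat == base.encode()) * weights[:, None]).sum(axis=0)
    totals = counts.sum(axis=1)
    fractions = pd.DataFrame(counts / totals[:, None], columns=list(BASES))
    positions = pd.DataFrame(
        {
            "codon_index": np.arange(n_pos) // 3,
            "slot": np.arange(n_pos) % 3 + 1,
            "n_observations": totals.astype(int),
        }
    )
    return CompositionProfile(fractions=fractions, positions=positions)


def composition_deviation(
    profile: CompositionProfile, design: LibraryDesign
) -> pd.DataFrame:
    """Per-position Pearson chi-square vs the ideal NNK expectation.

    Expected fractions are 1/4 per base at N slots (1, 2) and 1/2 for G and
    T at the K slot (3).  Returns one row per position with the statistic
    and per-base fold-over-expected (NaN where the expectation is 0).
    A statistic only — no p-values or multiplicity claims.
    """
    rows = []
    for pos in range(profile.n_positions):
        slot = int(profile.positions.loc[pos, "slot"])
        n_obs = float(profile.positions.loc[pos, "n_observations"])
        obs_frac = profile.fractions.loc[pos]
        if slot == 3:
            expected = {b: (0.5 if b in K_BASES else 0.0) for b in BASES}
        else:
            expected = {b: 0.25 for b in BASES}
        support = [b for b in BASES if expected[b] > 0]
        chi2 = float(
            stats.chisquare(
                [obs_frac[b] * n_obs for b in support],
                [expected[b] * n_obs for b in support],
            ).statistic
        )
        folds = {
            f"fold_{b}": obs_frac[b] / expected[b] if expected[b] > 0 else float("nan")
            for b in BASES
        }
        rows.append({"position": pos, "slot": slot, "chi2": chi2, **folds})
    return pd.DataFrame(rows).set_index("position")


#: class label for amber-derived glutamine, kept separate from CAG-encoded Q
Q_AMBER = "Q_amber"


def _aa_class(codon: str) -> str:
    """Map a codon to one of the 21 amber-aware residue classes.

    The classes are the 20 amino acids plus the additional glutamine that
    amber readthrough contributes — CAG-encoded Gln stays 'Q', TAG becomes
    'Q_amber'.  Non-suppressible stops map to '*'.
    """
    if codon == AMBER:
        return Q_AMBER
    return translate_codon(codon, amber_as_q=False)


def aa_class_degeneracy() -> dict[str, int]:
    """NNK codon multiplicity per amber-aware class (21 entries, sum 32)."""
    table: dict[str, int] = {}
    for codon in NNK_CODONS:
        cls = _aa_class(codon)
        if cls == "*":  # unreachable under NNK; kept for symmetry
            continue
        table[cls] = table.get(cls, 0) + 1
    return table


def normalized_aa_distribution(peps: PeptideTable) -> dict[str, float]:
    """Degeneracy-normalized residue frequencies over the random positions.

    Raw read-weighted counts per amber-aware class (20 amino acids plus the
    amber-derived glutamine, 21 classes in all) are divided by each class's
    NNK codon multiplicity and renormalized to sum to 1, so an exactly
    codon-uniform library scores 1/21 = 0.048 for every class — the flat
    reference line of a perfectly random library.  Stop ('*') positions,
    reachable only when NNK validation is bypassed, are excluded from the
    tally and the denominator.
    """
    if len(peps.rows) == 0:
        raise ValueError("empty peptide table")
    if not peps.amber_as_q:
        raise ValueError("normalized AA distribution requires amber_as_q translation")
    degeneracy = aa_class_degeneracy()
    design = peps.design
    counts: dict[str, float] = {}
    for _, row in peps.rows.iterrows():
        region = design.random_region(row["insert"])
        weight = row["count"]
        for i in range(0, len(region), 3):
            cls = _aa_class(region[i : i + 3])
            if cls == "*":
                continue
            counts[cls] = counts.get(cls, 0.0) + weight
    normalized = {cls: counts.get(cls, 0.0) / degeneracy[cls] for cls in degeneracy}
    total = sum(normalized.values())
    if total == 0:
        raise ValueError("no coding positions observed")
    return {cls: v / total for cls, v in sorted(normalized.items())}


def raw_aa_distribution(peps: PeptideTable) -> dict[str, float]:
    """Un-normalized residue frequencies (for transparency alongside the
    degeneracy-normalized version)."""
    if len(peps.rows) == 0:
        raise ValueError("empty peptide table")
    design = peps.design
    counts: dict[str, float] = {}
    total = 0.0
    for _, row in peps.rows.iterrows():
        region = design.random_region(row["insert"])
        for i in range(0, len(region), 3):
            aa = translate_codon(region[i : i + 3], amber_as_q=peps.amber_as_q)
            if aa == "*":
                continue
            counts[aa] = counts.get(aa, 0.0) + row["count"]
            total += row["count"]
    return {aa: v / total for aa, v in sorted(counts.items())}


def expected_uag_fraction(n_codons: int) -> float:
    """P(>=1 amber codon) in an n-codon equimolar NNK insert: 1-(31/32)^n."""
    if n_codons < 0:
        raise ValueError("n_codons must be >= 0")
    return 1.0 - (31.0 / 32.0) ** n_codons


def bias_adjusted_uag_expectation(profile: CompositionProfile) -> float:
    """P(>=1 TAG) under the observed per-slot base fractions.

    Secondary to :func:`expected_uag_fraction`: uses each codon's own
    observed T/A/G slot fractions instead of the ideal 1/32.
    """
    p_none = 1.0
    frac = profile.fractions
    for codon_start in range(0, profile.n_positions, 3):
        p_tag = (
            frac.loc[codon_start, "T"]
            * frac.loc[codon_start + 1, "A"]
            * frac.loc[codon_start + 2, "G"]
        )
        p_none *= 1.0 - p_tag
    return 1.0 - p_none


def overrepresentation_report(peps: PeptideTable, top_k: int = 20) -> pd.DataFrame:
    """Top peptides by read count with fold over the mean copy number.

    fold = count / (total / unique); candidates for "parasitic" clones that
    replicate or assemble better rather than reflecting synthesis diversity.
    Ties are broken lexicographically by peptide.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if len(peps.rows) == 0:
        return pd.DataFrame(columns=["peptide", "count", "fold"])
    mean_copy = peps.total_peptides / peps.unique_peptides
    df = (
        peps.rows.groupby("peptide", as_index=False)["count"]
        .sum()
        .sort_values(["count", "peptide"], ascending=[False, True])
        .head(top_k)
        .reset_index(drop=True)
    )
    df["fold"] = df["count"] / mean_copy
    return df


@dataclass
class BiasReport:
    """Roll-up of every randomness statistic for one sequenced library."""

    design_name: str
    n_random_codons: int
    constrained: bool
    total_reads: int
    accepted_reads: int
    total_peptides: int
    unique_peptides: int
    theoretical_complexity: float
    nnk_nucleotide_complexity: float
    stop_class_fractions_reads: dict[str, float]
    stop_class_fractions_unique: dict[str, float]
    uag_observed: float
    uag_expected: float
    uag_expected_bias_adjusted: float
    aa_normalized: dict[str, float]
    aa_raw: dict[str, float]
    composition: CompositionProfile
    deviation: pd.DataFrame
    top_overrepresented: pd.DataFrame
    rejected_by_reason: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "design_name",
                "n_random_codons",
                "constrained",
                "total_reads",
                "accepted_reads",
                "total_peptides",
                "unique_peptides",
                "theoretical_complexity",
                "nnk_nucleotide_complexity",
                "stop_class_fractions_reads",
                "stop_class_fractions_unique",
                "uag_observed",
                "uag_expected",
                "uag_expected_bias_adjusted",
                "aa_normalized",
                "aa_raw",
                "rejected_by_reason",
            )
        }
        d["composition_fractions"] = self.composition.fractions.to_dict(orient="list")
        d["composition_positions"] = self.composition.positions.to_dict(orient="list")
        d["deviation"] = self.deviation.reset_index().to_dict(orient="list")
        d["top_overrepresented"] = self.top_overrepresented.to_dict(orient="list")
        return d

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "BiasReport":
        composition = CompositionProfile(
            fractions=pd.DataFrame(d["composition_fractions"]),
            positions=pd.DataFrame(d["composition_positions"]),
        )
        deviation = pd.DataFrame(d["deviation"]).set_index("position")
        top = pd.DataFrame(d["top_overrepresented"], columns=["peptide", "count", "fold"])
        scalar = {
            k: v
            for k, v in d.items()
            if not k.startswith("composition_")
            and k not in ("deviation", "top_overrepresented")
        }
        return cls(
            composition=composition,
            deviation=deviation,
            top_overrepresented=top,
            **scalar,
        )

    @classmethod
    def from_json(cls, text: str) -> "BiasReport":
        return cls.from_dict(json.loads(text))


def build_bias_report(
    inserts: InsertTable, amber_as_q: bool = True, top_k: int = 20
) -> BiasReport:
    """Assemble the full diagnostics roll-up from a validated InsertTable."""
    if not inserts.counts:
        raise ValueError("empty insert table")
    design = inserts.design
    peps = tabulate(inserts, amber_as_q=amber_as_q)
    profile = nucleotide_composition(inserts)
    frac_reads = peps.class_fractions("reads")
    frac_unique = peps.class_fractions("unique")
    return BiasReport(
        design_name=design.name,
        n_random_codons=design.n_random_codons,
        constrained=design.constrained,
        total_reads=inserts.report.total_reads,
        accepted_reads=inserts.report.accepted,
        total_peptides=peps.total_peptides,
        unique_peptides=peps.unique_peptides,
        theoretical_complexity=float(theoretical_complexity(design)),
        nnk_nucleotide_complexity=float(nnk_nucleotide_complexity(design)),
        stop_class_fractions_reads=frac_reads,
        stop_class_fractions_unique=frac_unique,
        uag_observed=frac_reads["uag_only"],
        uag_expected=expected_uag_fraction(design.n_random_codons),
        uag_expected_bias_adjusted=bias_adjusted_uag_expectation(profile),
        aa_normalized=normalized_aa_distribution(peps) if amber_as_q else {},
        aa_raw=raw_aa_distribution(peps),
        composition=profile,
        deviation=composition_deviation(profile, design),
        top_overrepresented=overrepresentation_report(peps, top_k=top_k),
        rejected_by_reason=dict(inserts.report.rejected_by_reason),
    )


def codon_uniform_peptide_table() -> PeptideTable:
    """Analytic single-codon table with all 32 NNK codons at equal weight.

    The exact expectation object behind the flat 1/21 line: feeding it to
    :func:`normalized_aa_distribution` returns 1/21 per residue to machine
    precision.
    """
    design = LibraryDesign(name="analytic_nnk", n_random_codons=1)
    table = InsertTable(
        counts={c: 1 for c in NNK_CODONS},
        design=design,
        report=FilterReport(total_reads=32, accepted=32),
    )
    return tabulate(table, amber_as_q=True)
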