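"""Shared fixtures: small library designs and synthesis models."""

import numpy as np
import pytest

from nnkqc import LibraryDesign, SynthesisModel


@pytest.fixture
def linear3() -> LibraryDesign:
    """Minimal 3-codon linear design with no flanks."""
    return LibraryDesign(name="lin3", n_random_codons=3)


@pytest.fixture
def flanked7() -> LibraryDesign:
    """Linear 7-mer with barcode-bearing flanks, like a sequenced amplicon."""
    return LibraryDesign(
        name="7",
        n_random_codons=7,
        upstream_flank="ACGGTACCGGT",
        downstream_flank="GGTGGAGGTTCG",
        barcode="GTACC",
        barcode_offset=3,
    )


@pytest.fixture
def c10c() -> LibraryDesign:
    """Cysteine-looped 10-mer with flanks and barcode."""
    return LibraryDesign(
        name="C10C",
        n_random_codons=10,
        constrained=True,
        upstream_flank="ACGGTACCGGT",
        downstream_flank="GGTGGAGGTTCG",
        barcode="GTACC",
        barcode_offset=3,
    )


@pytest.fixture
def equal_model() -> SynthesisModel:
    return SynthesisModel()


@pytest.fixture
def g_biased_model() -> SynthesisModel:
    """Equimolar stock, G-favouring efficiencies (the uncalibrated chemistry)."""
    return SynthesisModel.g_biased()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
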