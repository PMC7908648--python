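"""Shared fixtures: small simulated genomes and evidence sets."""

from __future__ import annotations

import numpy as np
import pytest

from svtriage.coverage import estimate_genome_coverage
from svtriage.simulate import (
    PlantedVariant,
    SimulationConfig,
    simulate_sample,
)


@pytest.fixture
def small_config() -> SimulationConfig:
    """1.2-Mb single-contig genome with one variant of each type."""
    variants = (
        PlantedVariant("1", 100_000, 102_000, "DEL", "0/1"),
        PlantedVariant("1", 300_000, 310_000, "DUP", "0/1"),
        PlantedVariant("1", 500_000, 520_000, "INV", "0/1"),
        PlantedVariant("1", 700_000, 704_000, "DEL", "1/1"),
    )
    return SimulationConfig(
        contigs={"1": 1_200_000}, variants=variants, seed=42, noise_per_mb=0.0
    )


@pytest.fixture
def sample_evidence(small_config):
    evidence, truth = simulate_sample(small_config, sample_id="S1")
    return evidence, truth


@pytest.fixture
def genome_estimate(small_config, sample_evidence):
    evidence, _ = sample_evidence
    return estimate_genome_coverage(evidence.track, small_config.layout())


def write_sam(path, reads, contigs=(("1", 1_000_000), ("2", 1_000_000))):
    """Minimal coordinate-sorted SAM for extraction tests."""
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in contigs:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.extend(reads)
    path.write_text("\n".join(lines) + "\n")
    return path
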