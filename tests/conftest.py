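"""Shared fixtures: small ground-truthed stacks and the default cohort run."""

from __future__ import annotations

import zlib

import numpy as np
import pytest

from ihcmap.pipeline import analyze_cohort
from ihcmap.synth import (
    SyntheticStackSpec,
    generate_cohort,
    generate_stack,
    rect_zone,
)


def small_stack_spec(
    seed: int = 0,
    transforms: list[dict] | None = None,
    blob_counts: dict | None = None,
    artifact_counts: dict | None = None,
) -> SyntheticStackSpec:
    """A 1792x1792 DS2 stack: 2 class zones, submucosa strip, muscle band.

    With identity transforms the zones align exactly to the DS8 patch grid
    (DS8 canvas 448x448, 2x2 tiling; bottom row is submucosa+muscle).
    """
    zones = [
        rect_zone(0, 0, 896, 896, "Tissue", "Crypts"),
        rect_zone(896, 0, 1792, 896, "Tissue", "Inflammatory"),
        rect_zone(0, 896, 1792, 1120, "Submucosa"),
        rect_zone(0, 1120, 1792, 1792, "Muscle"),
    ]
    markers = ("CD8b", "CD3", "CD4")
    counts = blob_counts or {m: [6, 6, 0, 0] for m in markers}
    arts = artifact_counts if artifact_counts is not None else {m: [1, 1, 0, 0] for m in markers}
    steps = transforms if transforms is not None else [{} for _ in markers]
    return SyntheticStackSpec(
        canvas_size=(1792, 1792),
        zones=zones,
        blob_counts=counts,
        artifact_counts=arts,
        transforms=steps,
        seed=seed,
    )


def registration_stack_spec(seed: int = 0, transforms: list[dict] | None = None) -> SyntheticStackSpec:
    """2048x2048 stack with an off-center tissue block, for warp recovery."""
    zones = [
        rect_zone(512, 512, 1024, 1024, "Tissue", "Crypts"),
        rect_zone(1024, 512, 1536, 1024, "Tissue", "Inflammatory"),
        rect_zone(512, 1024, 1536, 1280, "Submucosa"),
        rect_zone(512, 1280, 1536, 1536, "Muscle"),
    ]
    markers = ("CD8b", "CD3", "CD4")
    steps = transforms if transforms is not None else [
        {"rotation_deg": 4.0, "translation": (30, -12)},
        {"rotation_deg": -3.0, "translation": (-20, 25)},
        {"rotation_deg": 5.0, "translation": (15, 10)},
    ]
    return SyntheticStackSpec(
        canvas_size=(2048, 2048),
        zones=zones,
        blob_counts={m: [10, 10, 0, 0] for m in markers},
        artifact_counts={m: [1, 1, 0, 0] for m in markers},
        transforms=steps,
        seed=seed,
    )


@pytest.fixture
def small_stack():
    return generate_stack(small_stack_spec())


@pytest.fixture(scope="session")
def registration_case():
    spec = registration_stack_spec()
    return generate_stack(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 3-condition, 2-mice-per-condition cohort at seed 0,
    analyzed end to end. Session-scoped: several tests read it."""
    mice, table = generate_cohort(seed=0)
    result = analyze_cohort(mice, release_sections=True)
    return mice, table, result


class HashPatchClassifier:
    """Deterministic stand-in whose involved confidence is a pure function of
    the patch bytes; used for accumulation oracles."""

    def predict(self, patch: np.ndarray):
        p = (zlib.crc32(np.ascontiguousarray(patch).tobytes()) % 1000) / 999.0
        return p, 1.0 - p

    def embed(self, patch: np.ndarray):
        rng = np.random.default_rng(zlib.crc32(np.ascontiguousarray(patch).tobytes()) & 0x7FFFFFFF)
        return rng.normal(size=512)
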