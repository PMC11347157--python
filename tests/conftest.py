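"""Shared fixtures: small synthetic transcriptomes and annotation helpers."""

from __future__ import annotations

import pytest

from ribodwell.models import TranscriptModel
from ribodwell.simulate import generate_transcriptome


def annotation_of(transcripts: list[TranscriptModel]) -> dict:
    out = {}
    for t in transcripts:
        feats = {"CDS": t.cds}
        for i, u in enumerate(t.uorfs, start=1):
            feats[f"uORF{i}"] = u
        out[t.id] = feats
    return out


def sequences_of(transcripts: list[TranscriptModel]) -> dict[str, str]:
    return {t.id: t.sequence for t in transcripts}


@pytest.fixture(scope="session")
def small_transcriptome() -> list[TranscriptModel]:
    """20 equal-abundance transcripts, mean CDS 300 nt."""
    return generate_transcriptome(20, seed=11, abundance_sigma=0)


@pytest.fixture(scope="session")
def weighted_transcriptome() -> list[TranscriptModel]:
    """50 transcripts with log-normal abundances (the generator default)."""
    return generate_transcriptome(50, seed=12)
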