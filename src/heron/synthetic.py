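"""Seeded synthetic tiled-proteome array datasets with known truth.

The generator emulates the shape of normalized peptide-array data: a set of
proteins tiled by 16-mer probes at a 1/2/4 amino-acid step, approximately
normal per-probe normalized intensities, contiguous high-binding epitope
regions planted in a subset ("carriers") of the positive samples, and
technical-replicate pairs made by adding independent noise.  Intensities
are on an arbitrary normalized scale with background N(mean, sd) i.i.d.
per cell (an optional AR(1) mode correlates noise along each protein, as in
smoothed array data); planted effects are additive and constant across the
planted interval, with an optional triangular taper at the edges for
boundary-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import NEGATIVE, PEPTIDE_LENGTH, POSITIVE, Epitope, ProbeDataset

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class PlantedEpitope:
    """A contiguous high-binding region: protein positions [start, end] (1-based, a.a.)."""

    protein_id: str
    start: int
    end: int
    effect: float = 6.0
    carriers: tuple[str, ...] = ()


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    Defaults are the conditions used throughout the test-bench: 5 negative
    and 6 positive samples, 2-a.a. tiling, planted effects of 6 background
    SDs carried by 3 of the positive samples.
    """

    n_proteins: int = 6
    protein_length_range: tuple[int, int] = (60, 110)
    tiling: int = 2
    n_negative: int = 5
    n_positive: int = 6
    background_mean: float = 0.0
    background_sd: float = 1.0
    effect: float = 6.0
    n_carriers: int = 3
    n_planted: int = 2
    planted_length: int = 20
    planted_epitopes: list[PlantedEpitope] | None = None
    replicate_noise_sd: float = 0.1
    ar1_rho: float = 0.0
    taper: bool = False
    seed: int = 0

    def positive_names(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_positive)]

    def negative_names(self) -> list[str]:
        return [f"N{i + 1}" for i in range(self.n_negative)]


@dataclass
class SynthTruth:
    """Planted intervals, their probe-level footprint, and per-probe labels."""

    planted: list[PlantedEpitope]
    #: planted regions expressed as probe blocks (the boundary ground truth)
    true_epitopes: list[Epitope]
    #: probes x positive-samples boolean signal indicator
    signal: pd.DataFrame


def _tile_protein(length: int, tiling: int) -> np.ndarray:
    """1-based start positions of the 16-mers tiling a protein of `length` a.a."""
    if length < PEPTIDE_LENGTH:
        return np.array([], dtype=int)
    return np.arange(1, length - PEPTIDE_LENGTH + 2, tiling, dtype=int)


def _default_planting(
    config: SynthConfig,
    lengths: dict[str, int],
    rng: np.random.Generator,
) -> list[PlantedEpitope]:
    """Plant `n_planted` non-overlapping intervals on distinct proteins."""
    positives = config.positive_names()
    planted = []
    proteins = list(lengths)
    for i in range(config.n_planted):
        protein = proteins[i % len(proteins)]
        length = lengths[protein]
        span = min(config.planted_length, length - PEPTIDE_LENGTH)
        hi = length - span
        start = int(rng.integers(1, hi + 1))
        carriers = tuple(
            sorted(rng.choice(positives, size=config.n_carriers, replace=False))
        )
        planted.append(
            PlantedEpitope(protein, start, start + span - 1, config.effect, carriers)
        )
    return planted


def generate(config: SynthConfig) -> tuple[ProbeDataset, SynthTruth]:
    """Generate a dataset and its truth; bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length_range
    proteins = [f"PROT{i + 1:03d}" for i in range(config.n_proteins)]
    lengths = {p: int(rng.integers(lo, hi + 1)) for p in proteins}
    sequences = {
        p: "".join(rng.choice(AMINO_ACIDS, size=lengths[p])) for p in proteins
    }

    meta_rows = []
    for p in proteins:
        for start in _tile_protein(lengths[p], config.tiling):
            meta_rows.append(
                (
                    f"{p};{start:04d}",
                    p,
                    int(start),
                    config.tiling,
                    sequences[p][start - 1 : start - 1 + PEPTIDE_LENGTH],
                )
            )
    probe_meta = pd.DataFrame(
        meta_rows, columns=["probe_id", "protein_id", "start", "tiling", "sequence"]
    ).set_index("probe_id")

    samples = config.negative_names() + config.positive_names()
    labels = pd.Series(
        [NEGATIVE] * config.n_negative + [POSITIVE] * config.n_positive, index=samples
    )

    n_probes = len(probe_meta)
    noise = rng.normal(0.0, 1.0, size=(n_probes, len(samples)))
    if config.ar1_rho:
        rho = config.ar1_rho
        protein_col = probe_meta["protein_id"].to_numpy()
        for i in range(1, n_probes):
            if protein_col[i] == protein_col[i - 1]:
                noise[i] = rho * noise[i - 1] + np.sqrt(1 - rho**2) * noise[i]
    intensities = pd.DataFrame(
        config.background_mean + config.background_sd * noise,
        index=probe_meta.index,
        columns=samples,
    )

    planted = config.planted_epitopes
    if planted is None:
        planted = _default_planting(config, lengths, rng)
    for epi in planted:
        if epi.protein_id not in lengths:
            raise ValueError(f"planted epitope on unknown protein {epi.protein_id!r}")
        if not (1 <= epi.start <= epi.end <= lengths[epi.protein_id]):
            raise ValueError(
                f"planted interval [{epi.start}, {epi.end}] outside {epi.protein_id}"
            )
        if epi.effect < 0:
            raise ValueError("planted effect must be non-negative")

    positives = config.positive_names()
    signal = pd.DataFrame(False, index=probe_meta.index, columns=positives)
    true_epitopes = []
    for epi in planted:
        mask = (
            (probe_meta["protein_id"] == epi.protein_id)
            & (probe_meta["start"] <= epi.end)
            & (probe_meta["start"] + PEPTIDE_LENGTH - 1 >= epi.start)
        )
        member_ids = probe_meta.index[mask]
        if not len(member_ids):
            continue
        starts = probe_meta.loc[member_ids, "start"]
        bump = np.full(len(member_ids), epi.effect * config.background_sd)
        if config.taper:
            # linear ramp over the probes that only partially overlap the interval
            overlap = (
                np.minimum(starts + PEPTIDE_LENGTH - 1, epi.end)
                - np.maximum(starts, epi.start)
                + 1
            ) / PEPTIDE_LENGTH
            bump = bump * np.clip(overlap.to_numpy(), 0.0, 1.0)
        for sample in epi.carriers:
            intensities.loc[member_ids, sample] += bump
            signal.loc[member_ids, sample] = True
        true_epitopes.append(
            Epitope(
                protein_id=epi.protein_id,
                first=int(starts.iloc[0]),
                last=int(starts.iloc[-1]),
                member_probes=tuple(member_ids),
            )
        )

    data = ProbeDataset(intensities=intensities, sample_labels=labels, probe_meta=probe_meta)
    truth = SynthTruth(planted=list(planted), true_epitopes=true_epitopes, signal=signal)
    return data, truth


def make_replicate(data: ProbeDataset, noise_sd: float, seed: int = 0) -> ProbeDataset:
    """A technical replicate: the same dataset plus independent normal noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    intensities = data.intensities + rng.normal(0.0, noise_sd, size=data.intensities.shape)
    return ProbeDataset(
        intensities=intensities,
        sample_labels=data.sample_labels.copy(),
        probe_meta=data.probe_meta.copy(),
    )
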