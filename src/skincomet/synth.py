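"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators emulate the study's data types:

* :func:`simulate_panel` — reference proteomes with planted orthologous
  families (point substitutions, occasional indels, recent within-genome
  duplicates) plus unrelated decoy proteins, with the planted genome x
  family copy-number matrix recorded as truth;
* :func:`simulate_community` — an OTU table with one OTU per panel
  genome, log-normal relative abundances, a multiplicative group effect
  on designated OTUs and multinomial sampling to a fixed depth (emulating
  the two-age-group cheek-swab design, 25 subjects per group);
* :func:`simulate_phenotypes` — the eight clinical measurements as noisy
  linear readouts of a latent age variable (evenness loading negative).

All outputs are bit-reproducible from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .infer16s import OtuTable
from .phmm import DEFAULT_BACKGROUND
from .seqio import AA20, LabeledMatrix, NormState, ProteinRecord, ValidationError
from .skinstats import EIGHT_MEASUREMENTS


@dataclass
class SynthTruth:
    """Ground truth emitted alongside fixtures; sufficient to score every
    pipeline stage without re-deriving anything."""

    copy_numbers: dict[str, dict[str, int]] = field(default_factory=dict)
    family_members: dict[str, list[list[str]]] = field(default_factory=dict)
    otu_genome_map: dict[str, str] = field(default_factory=dict)
    group_labels: dict[str, str] = field(default_factory=dict)
    effect_otus: list[str] = field(default_factory=list)
    latent_age: dict[str, float] = field(default_factory=dict)
    loadings: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def copy_number_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.copy_numbers).T.sort_index().fillna(0).astype(int)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length, p=DEFAULT_BACKGROUND))


def _check_rate(name: str, value: float) -> None:
    if not 0.0 <= value <= 0.5:
        raise ValidationError(f"{name} must be in [0, 0.5], got {value}")


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float,
            indel_rate: float) -> str:
    """One derived copy: i.i.d. substitutions (uniform over the 19
    alternatives) and geometric-length indels at the stated per-site
    rates."""
    aa = list(AA20)
    result: list[str] = []
    skip = 0  # residues remaining in an active deletion run
    for c in seq:
        r = rng.random()
        if r < indel_rate / 2 and skip == 0:   # start a deletion run
            skip = int(rng.geometric(0.5))
        elif r < indel_rate:                   # insertion before this residue
            result.append(_random_sequence(rng, int(rng.geometric(0.5))))
        if skip > 0:
            skip -= 1
            continue
        if rng.random() < sub_rate:
            result.append(str(rng.choice([a for a in aa if a != c])))
        else:
            result.append(c)
    s = "".join(result)
    return s if s else seq[:1]


def evolve_family(seed_seq: str, n_copies: int, sub_rate: float = 0.15,
                  indel_rate: float = 0.0, seed: int = 0) -> list[str]:
    """Derive ``n_copies`` family members from a seed sequence.

    Deterministic given the seed; with both rates zero every copy equals
    the seed.
    """
    _check_rate("sub_rate", sub_rate)
    _check_rate("indel_rate", indel_rate)
    if not seed_seq:
        raise ValidationError("empty seed sequence")
    rng = np.random.default_rng(seed)
    return [_mutate(rng, seed_seq, sub_rate, indel_rate) for _ in range(n_copies)]


def simulate_panel(n_genomes: int = 10, n_families: int = 12,
                   seq_len: int = 250, decoys_per_genome: int = 5,
                   sub_rate: float = 0.15, indel_rate: float = 0.01,
                   dup_divergence: float = 0.02,
                   p_absent: float = 0.15, p_double: float = 0.15,
                   family_names: Sequence[str] | None = None,
                   seed: int = 17) -> tuple[dict[str, list[ProteinRecord]], SynthTruth]:
    """Reference proteomes with planted orthologous families.

    Per genome and family the copy number is 0/1/2 with probabilities
    (p_absent, 1-p_absent-p_double, p_double); every family is forced to
    be present in at least two genomes so a model can be trained.  Second
    copies are recent duplicates of the genome's first copy (divergence
    ``dup_divergence``), matching the in-paralog definition.  Decoys are
    unrelated background-composition sequences.
    """
    if family_names is None:
        family_names = [f"fam{i:02d}" for i in range(1, n_families + 1)]
    if len(family_names) != n_families:
        raise ValidationError("family_names length must equal n_families")
    rng = np.random.default_rng(seed)
    genome_ids = [f"g{i:02d}" for i in range(1, n_genomes + 1)]
    seeds = {f: _random_sequence(rng, seq_len) for f in family_names}

    copy_matrix = rng.choice([0, 1, 2], size=(n_genomes, n_families),
                             p=[p_absent, 1 - p_absent - p_double, p_double])
    for j in range(n_families):
        present = np.flatnonzero(copy_matrix[:, j] > 0)
        while len(present) < 2:
            g = int(rng.integers(n_genomes))
            copy_matrix[g, j] = max(copy_matrix[g, j], 1)
            present = np.flatnonzero(copy_matrix[:, j] > 0)

    truth = SynthTruth(seed=seed)
    proteomes: dict[str, list[ProteinRecord]] = {g: [] for g in genome_ids}
    for j, fam in enumerate(family_names):
        truth.family_members[fam] = []
        for i, gid in enumerate(genome_ids):
            cn = int(copy_matrix[i, j])
            truth.copy_numbers.setdefault(gid, {})[fam] = cn
            if cn == 0:
                continue
            lineage = _mutate(rng, seeds[fam], sub_rate, indel_rate)
            copies = [lineage]
            for extra in range(cn - 1):
                copies.append(_mutate(rng, lineage, dup_divergence, 0.0))
            for c_idx, seq in enumerate(copies, start=1):
                pid = f"{fam}_{gid}_c{c_idx}"
                proteomes[gid].append(ProteinRecord(pid, gid, seq))
                truth.family_members[fam].append([gid, pid])
    for gid in genome_ids:
        for d in range(1, decoys_per_genome + 1):
            length = int(rng.integers(int(seq_len * 0.8), int(seq_len * 1.2) + 1))
            pid = f"decoy_{gid}_d{d:02d}"
            proteomes[gid].append(ProteinRecord(pid, gid, _random_sequence(rng, length)))
    return proteomes, truth


def _default_taxonomy(genome_ids: Sequence[str]) -> dict[str, str]:
    return {g: ("k__Bacteria;p__Firmicutes;c__Bacilli;o__Bacillales;"
                f"f__Synthaceae;g__Genus_{g};s__species_{g}")
            for g in genome_ids}


def simulate_community(genome_ids: Sequence[str], n_samples: int = 50,
                       effect_otus: Sequence[str] | None = None,
                       effect_size: float = 3.0,
                       sigma_base: float = 1.0, dispersion: float = 0.5,
                       depth: int = 20000,
                       seed: int = 17) -> tuple[OtuTable, SynthTruth]:
    """A samples x OTUs count table with two-group structure.

    One OTU per panel genome.  Per-sample log abundances are the OTU's
    community-wide base level plus sample noise; samples in the second
    ('old') group get ``log(effect_size)`` added on the designated effect
    OTUs.  Counts are multinomial at the given depth.  An ``effect_size``
    of 1 plants no effect.
    """
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    if n_samples < 2:
        raise ValidationError("need at least two samples")
    rng = np.random.default_rng(seed)
    otu_ids = [f"OTU_{g}" for g in genome_ids]
    effect = list(effect_otus) if effect_otus is not None else []
    unknown = [o for o in effect if o not in otu_ids]
    if unknown:
        raise ValidationError(f"unknown effect OTUs: {unknown}")
    base = rng.normal(0.0, sigma_base, size=len(otu_ids))
    half = n_samples // 2
    sample_ids = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    groups = ["young"] * half + ["old"] * (n_samples - half)
    counts = np.zeros((n_samples, len(otu_ids)), dtype=float)
    eff_idx = [otu_ids.index(o) for o in effect]
    for i in range(n_samples):
        logab = base + rng.normal(0.0, dispersion, size=len(otu_ids))
        if groups[i] == "old":
            logab[eff_idx] += np.log(effect_size)
        p = np.exp(logab)
        p /= p.sum()
        counts[i] = rng.multinomial(depth, p)
    df = pd.DataFrame(counts, index=sample_ids, columns=otu_ids)
    taxonomy = {f"OTU_{g}": tax for g, tax in _default_taxonomy(genome_ids).items()}
    otus = OtuTable(LabeledMatrix(df, NormState.raw_counts), taxonomy)
    truth = SynthTruth(
        otu_genome_map={f"OTU_{g}": g for g in genome_ids},
        group_labels=dict(zip(sample_ids, groups)),
        effect_otus=effect,
        seed=seed,
    )
    return otus, truth


def simulate_phenotypes(n_subjects: int = 50,
                        loadings: dict[str, float] | None = None,
                        noise_sd: float = 0.5,
                        seed: int = 17) -> tuple[pd.DataFrame, SynthTruth]:
    """The eight clinical measurements as linear readouts of latent age.

    Each measurement = loading x latent age + Gaussian noise; skin color
    evenness gets a negative loading by default (evenness decreases with
    aging).  Latent age is standard normal.
    """
    if n_subjects < 3:
        raise ValidationError("need at least three subjects")
    load = {m: (-1.0 if m == "skin_color_evenness" else 1.0)
            for m in EIGHT_MEASUREMENTS}
    if loadings:
        load.update(loadings)
    rng = np.random.default_rng(seed)
    subjects = [f"subj{i:03d}" for i in range(1, n_subjects + 1)]
    latent = rng.normal(0.0, 1.0, size=n_subjects)
    data = {}
    for m in EIGHT_MEASUREMENTS:
        data[m] = load[m] * latent + rng.normal(0.0, noise_sd, size=n_subjects)
    df = pd.DataFrame(data, index=subjects)
    truth = SynthTruth(latent_age=dict(zip(subjects, map(float, latent))),
                       loadings=load, seed=seed)
    return df, truth
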