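"""Synthetic multi-locus barcoding datasets with known taxonomy.

Sequences evolve down a three-level star-shaped genealogy: a uniform-random
root per locus, genus ancestors derived from it by independent per-site
substitution at ``genus_divergence``, species ancestors from their genus
ancestor at ``species_divergence``, and individuals from their species
ancestor at ``individual_divergence``. Substitutions are Jukes-Cantor style
(uniform over the three alternative bases), with no rate heterogeneity.
Loci with ``indel_rate > 0`` additionally gain short insertion/deletion
runs (1-5 bp, geometric) on every branch, emulating non-coding spacers such
as trnH-psbA where indels are common and alignment is ambiguous.

The easy preset (5 genera x 3 species x 3 individuals; loci of 800, 550 and
450 bp with indels only in the spacer; divergences 0.10 / 0.02 / 0.002)
produces datasets whose taxonomy a correct pipeline should recover almost
perfectly; the degraded preset collapses the species level into the
individual level, so species monophyly becomes close to arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .sequence_io import LocusRecord, MultiLocusDataset, TaxonLabel, assemble_dataset

__all__ = [
    "LocusSpec",
    "SimConfig",
    "TruthRecord",
    "easy_preset",
    "degraded_preset",
    "simulate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class LocusSpec:
    """Length model and indel propensity of one simulated locus."""

    name: str
    mean_length: int
    length_sd: float = 0.0
    indel_rate: float = 0.0  # expected indel events per site per branch


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; divergences are per-site substitution probabilities."""

    n_genera: int = 5
    species_per_genus: int = 3
    individuals_per_species: int = 3
    locus_specs: tuple[LocusSpec, ...] = (
        LocusSpec("matK", 800, 10.0),
        LocusSpec("rbcL", 550, 8.0),
        LocusSpec("trnH-psbA", 450, 15.0, indel_rate=0.002),
    )
    genus_divergence: float = 0.10
    species_divergence: float = 0.02
    individual_divergence: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genera, self.species_per_genus, self.individuals_per_species) < 1:
            raise ValueError("taxon counts must be positive")
        if not self.locus_specs:
            raise ValueError("at least one locus is required")
        for p in (
            self.genus_divergence,
            self.species_divergence,
            self.individual_divergence,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"divergence {p} outside [0, 1]")

    def to_json_dict(self) -> dict:
        return {
            "n_genera": self.n_genera,
            "species_per_genus": self.species_per_genus,
            "individuals_per_species": self.individuals_per_species,
            "loci": [
                {
                    "name": s.name,
                    "mean_length": s.mean_length,
                    "length_sd": s.length_sd,
                    "indel_rate": s.indel_rate,
                }
                for s in self.locus_specs
            ],
            "genus_divergence": self.genus_divergence,
            "species_divergence": self.species_divergence,
            "individual_divergence": self.individual_divergence,
            "seed": self.seed,
        }


def easy_preset(seed: int = 0) -> SimConfig:
    """Well-separated hierarchy: divergences 0.10 / 0.02 / 0.002."""
    cfg = SimConfig(seed=seed)
    assert (
        cfg.genus_divergence > cfg.species_divergence > cfg.individual_divergence
    )
    return cfg


def degraded_preset(seed: int = 0) -> SimConfig:
    """Species level collapsed onto the individual level.

    species_divergence ~ individual_divergence, so conspecific sequences are
    no more similar to each other than to congeneric heterospecifics —
    species monophyly in the reconstructed tree degrades accordingly.
    """
    return replace(easy_preset(seed), species_divergence=0.002)


@dataclass(frozen=True)
class TruthRecord:
    """Full simulated genealogy: ancestor sequences at every level."""

    roots: dict[str, str]                            # locus -> root sequence
    genus_ancestors: dict[tuple[str, str], str]      # (locus, genus) -> seq
    species_ancestors: dict[tuple[str, str, str], str] = field(repr=False)


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p, uniformly to another base."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < p)[0]
    if hits.size:
        # add 1..3 mod 4 in base-code space: always a different base
        codes = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(codes + rng.integers(1, 4, hits.size)) % 4]
    return out


def _apply_indels(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    if rate <= 0.0:
        return seq
    n_events = rng.poisson(rate * seq.size)
    for _ in range(n_events):
        run = min(int(rng.geometric(0.5)), 5)
        if rng.random() < 0.5 and seq.size > run:  # deletion
            pos = int(rng.integers(0, seq.size - run))
            seq = np.delete(seq, slice(pos, pos + run))
        else:  # insertion
            pos = int(rng.integers(0, seq.size + 1))
            seq = np.insert(seq, pos, _BASES[rng.integers(0, 4, run)])
    return seq


def _derive(
    parent: np.ndarray,
    divergence: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    return _apply_indels(_mutate(parent, divergence, rng), indel_rate, rng)


def _to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode("ascii")


def simulate_dataset(config: SimConfig) -> tuple[MultiLocusDataset, TruthRecord]:
    """Simulate a complete multi-locus dataset; deterministic for a seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genera = [f"Genus{chr(ord('A') + i % 26)}{i // 26 or ''}" for i in range(config.n_genera)]
    species = [f"sp{j + 1}" for j in range(config.species_per_genus)]
    individuals = [f"{k + 1:02d}" for k in range(config.individuals_per_species)]

    roots: dict[str, str] = {}
    genus_anc: dict[tuple[str, str], str] = {}
    species_anc: dict[tuple[str, str, str], str] = {}
    per_locus: dict[str, list[LocusRecord]] = {loc.name: [] for loc in config.locus_specs}

    for spec in config.locus_specs:
        L = max(int(round(rng.normal(spec.mean_length, spec.length_sd))), 50)
        root = _BASES[rng.integers(0, 4, L)]
        roots[spec.name] = _to_str(root)
        for genus in genera:
            g_seq = _derive(root, config.genus_divergence, spec.indel_rate, rng)
            genus_anc[(spec.name, genus)] = _to_str(g_seq)
            for sp in species:
                s_seq = _derive(g_seq, config.species_divergence, spec.indel_rate, rng)
                species_anc[(spec.name, genus, sp)] = _to_str(s_seq)
                for ind in individuals:
                    i_seq = _derive(
                        s_seq, config.individual_divergence, spec.indel_rate, rng
                    )
                    label = TaxonLabel(
                        genus=genus,
                        species=sp,
                        individual=ind,
                        sequence_id=f"{genus}_{sp}_{ind}",
                    )
                    per_locus[spec.name].append(
                        LocusRecord(
                            label=label, locus=spec.name, residues=_to_str(i_seq)
                        )
                    )

    dataset = assemble_dataset(per_locus, strict=True)
    return dataset, TruthRecord(
        roots=roots, genus_ancestors=genus_anc, species_ancestors=species_anc
    )
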