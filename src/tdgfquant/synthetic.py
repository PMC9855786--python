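"""Ground-truthed synthetic communities for end-to-end validation.

Emulates the source experiment's design: a defined 14-species gut
community colonizing gnotobiotic mice under three dietary regimes —
fiber-rich (R, 4 mice), fiber-free (F, 3 mice), and alternating (FR,
6 mice) — with 16S relative abundances for all 13 mice and
metatranscriptomic contig abundances for 3 randomly chosen mice per diet.

Each species carries, for every functional group it belongs to, one contig
holding a diverged ortholog of the group's marker protein (reverse
translated, random UTR flanks, random strand), plus decoy contigs of
uniform random composition.  Expression responds to diet through per-group
multipliers; per-sample community composition comes from a symmetric
Dirichlet, and per-contig lognormal noise models biological variability.
Every generated quantity is recorded in a ground-truth object so the
pipeline's estimates can be checked against what was simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .align import reverse_complement
from .catalog import Catalog
from .io_tables import (
    AbundanceTable,
    SampleMetadata,
    TaxonAbundanceTable,
    write_16s_table,
    write_abundance_table,
    write_sample_metadata,
)

__all__ = [
    "CommunitySpec",
    "Community",
    "GroundTruth",
    "SimulatedExperiment",
    "DEFAULT_GROUP_ASSIGNMENT",
    "mutate_to_identity",
    "reverse_translate",
    "generate_community",
    "simulate_expression",
    "write_experiment",
]

# Community membership emulating the 14-species model community and its
# partition into the four modeled groups (three members stay unclassified).
# The assignment is an illustrative default for simulation, not a curated
# annotation of the real strains.
DEFAULT_GROUP_ASSIGNMENT: dict[str, tuple[str, ...]] = {
    "Akkermansia muciniphila": ("mucin_degraders",),
    "Bacteroides caccae": ("mucin_degraders",),
    "Bacteroides ovatus": (),
    "Bacteroides thetaiotaomicron": ("mucin_degraders",),
    "Bacteroides uniformis": (),
    "Barnesiella intestinihominis": ("mucin_degraders",),
    "Clostridium symbiosum": ("butyrate_producers",),
    "Collinsella aerofaciens": ("acetogens",),
    "Desulfovibrio piger": ("sulfate_reducers",),
    "Escherichia coli HS": (),
    "Eubacterium rectale": ("butyrate_producers",),
    "Faecalibacterium prausnitzii": ("butyrate_producers",),
    "Marvinbryantia formatexigens": ("acetogens",),
    "Roseburia intestinalis": ("butyrate_producers",),
}

# Diet response of marker expression, encoding the qualitative pattern the
# method is meant to recover: mucin degraders and sulfate reducers strongly
# suppressed under the fiber-rich diet, butyrate producers' marker
# expression reduced, acetogens most active when sulfate reduction is down.
DEFAULT_DIET_MULTIPLIERS: dict[tuple[str, str], float] = {
    ("mucin_degraders", "F"): 1.0,
    ("mucin_degraders", "FR"): 1.0,
    ("mucin_degraders", "R"): 0.3,
    ("sulfate_reducers", "F"): 1.0,
    ("sulfate_reducers", "FR"): 1.0,
    ("sulfate_reducers", "R"): 0.4,
    ("butyrate_producers", "F"): 1.0,
    ("butyrate_producers", "FR"): 0.8,
    ("butyrate_producers", "R"): 0.5,
    ("acetogens", "F"): 0.5,
    ("acetogens", "FR"): 0.8,
    ("acetogens", "R"): 1.0,
}

#: 16S cohort sizes per diet (every mouse gets a 16S profile).
DEFAULT_MICE_PER_DIET: dict[str, int] = {"F": 3, "R": 4, "FR": 6}

# One fixed codon per amino acid for reverse translation; codon-usage
# realism is irrelevant to a protein-space search.
CODON_FOR_AA: dict[str, str] = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
    "X": "NNN",
}

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class CommunitySpec:
    """Design of one simulated experiment.

    ``tdgf_identity`` sets where marker orthologs land relative to the
    score threshold; ``diet_multipliers`` encode the diet response of each
    group's marker expression; ``lognormal_sigma`` is the sd (log scale) of
    per-contig biological noise; ``dirichlet_alpha`` the concentration of
    per-mouse community composition (larger = more even, less variable).
    """

    group_assignment: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_ASSIGNMENT)
    )
    tdgf_identity: float = 0.85
    n_decoy_contigs: int = 3
    diet_multipliers: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_DIET_MULTIPLIERS)
    )
    lognormal_sigma: float = 0.2
    dirichlet_alpha: float = 10.0
    mice_per_diet: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MICE_PER_DIET)
    )
    n_rnaseq_mice_per_diet: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.3 < self.tdgf_identity <= 1.0:
            raise ValueError("tdgf_identity must lie in (0.3, 1.0]")
        if any(m <= 0 for m in self.diet_multipliers.values()):
            raise ValueError("diet multipliers must be > 0")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")
        groups_with_members = {
            g for gs in self.group_assignment.values() for g in gs
        }
        for group, _diet in self.diet_multipliers:
            if group not in groups_with_members:
                raise ValueError(f"multiplier for memberless group {group!r}")

    @property
    def n_species(self) -> int:
        return len(self.group_assignment)

    @property
    def species(self) -> list[str]:
        return sorted(self.group_assignment)

    def multiplier(self, group: str, diet: str) -> float:
        return float(self.diet_multipliers.get((group, diet), 1.0))


@dataclass
class Community:
    """Generated contigs plus per-contig provenance."""

    contigs: dict[str, str]
    contig_info: pd.DataFrame  # index contig_id; species, is_tdgf, tdgf_id,
    #                            group_id, base_rate, length
    species_codes: dict[str, str]  # species name -> short code


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    species_abundance: pd.DataFrame  # species x all mice (16S truth)
    rnaseq_samples: list[str]
    contig_info: pd.DataFrame
    #: noise-free expected marker activity per (group, diet): the per-diet
    #: mean over RNA-seq mice of sum over member species of
    #: abundance x base_rate x multiplier
    group_activity: pd.DataFrame  # groups x diets
    #: the same activities expressed as per-mouse shares of the four
    #: groups' total, averaged per diet (distinguished-groups truth)
    group_activity_share: pd.DataFrame  # groups x diets

    def ranking(self, diet: str) -> tuple[str, ...]:
        """Groups ordered by decreasing true share under the given diet."""
        shares = self.group_activity_share[diet]
        return tuple(shares.sort_values(ascending=False, kind="stable").index)

    def to_json_dict(self) -> dict:
        return {
            "species_abundance": {
                s: self.species_abundance[s].to_dict()
                for s in self.species_abundance.columns
            },
            "rnaseq_samples": self.rnaseq_samples,
            "contigs": self.contig_info.reset_index().to_dict(orient="records"),
            "group_activity": {
                d: self.group_activity[d].to_dict()
                for d in self.group_activity.columns
            },
            "group_activity_share": {
                d: self.group_activity_share[d].to_dict()
                for d in self.group_activity_share.columns
            },
        }


@dataclass
class SimulatedExperiment:
    community: Community
    tables: dict[str, AbundanceTable]  # RNA-seq samples only
    s16: TaxonAbundanceTable  # all mice
    metadata: SampleMetadata  # all mice
    truth: GroundTruth

    @property
    def rnaseq_metadata(self) -> SampleMetadata:
        return self.metadata.restrict(list(self.tables))


def _positive_neighbors(matrix) -> dict[str, list[str]]:
    """For each amino acid, the different residues scoring > 0 against it."""
    out: dict[str, list[str]] = {}
    for aa in _AA20:
        out[aa] = [b for b in _AA20 if b != aa and matrix[aa, b] > 0]
    return out


def mutate_to_identity(
    protein: str, identity: float, seed: int | np.random.Generator
) -> str:
    """Substitute exactly ``round((1-identity)*L)`` positions.

    Positions are drawn uniformly without replacement; replacements come
    from the residue's BLOSUM62-positive neighbors when any exist
    (conservative substitutions, as between orthologs), otherwise uniformly
    from the other 19 residues.  Fully deterministic given the seed.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must lie in (0, 1]")
    if len(protein) < 10:
        raise ValueError("protein too short to mutate (< 10 aa)")
    from Bio.Align import substitution_matrices

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_sub = int(round((1 - identity) * len(protein)))
    if n_sub == 0:
        return protein
    neighbors = _positive_neighbors(substitution_matrices.load("BLOSUM62"))
    positions = rng.choice(len(protein), size=n_sub, replace=False)
    seq = list(protein)
    for pos in sorted(int(p) for p in positions):
        aa = seq[pos]
        pool = neighbors.get(aa) or [b for b in _AA20 if b != aa]
        seq[pos] = pool[int(rng.integers(len(pool)))]
    return "".join(seq)


def reverse_translate(protein: str) -> str:
    """Nucleotide coding sequence using one fixed codon per amino acid."""
    return "".join(CODON_FOR_AA[aa] for aa in protein)


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def generate_community(spec: CommunitySpec, catalog: Catalog) -> Community:
    """Build the contig set: marker-bearing contigs plus decoys per species.

    Every group in the catalog must have at least one member species in the
    spec.  Marker contigs embed a diverged ortholog of the group's single
    marker with random UTR flanks on a random strand; decoys are uniform
    random nucleotide sequences (their best alignment scores sit far below
    the score threshold for realistic marker lengths).
    """
    assigned = {g for gs in spec.group_assignment.values() for g in gs}
    missing = set(catalog.groups) - assigned
    if missing:
        raise ValueError(
            f"catalog groups without any member species in spec: {sorted(missing)}"
        )
    rng = np.random.default_rng(spec.seed)
    species_codes = {
        name: f"sp{i + 1:02d}" for i, name in enumerate(spec.species)
    }
    contigs: dict[str, str] = {}
    rows = []
    for name in spec.species:
        code = species_codes[name]
        for group_id in sorted(spec.group_assignment[name]):
            if group_id not in catalog.groups:
                continue
            tdgf = catalog.single_tdgf(group_id)
            ortholog = mutate_to_identity(tdgf.protein_seq, spec.tdgf_identity, rng)
            cds = reverse_translate(ortholog)
            left = _random_nt(rng, int(rng.integers(30, 91)))
            right = _random_nt(rng, int(rng.integers(30, 91)))
            seq = left + cds + right
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            cid = f"{code}.{tdgf.id}.tdgf"
            contigs[cid] = seq
            rows.append(
                {
                    "contig_id": cid,
                    "species": name,
                    "is_tdgf": True,
                    "tdgf_id": tdgf.id,
                    "group_id": group_id,
                    "base_rate": 1.0,
                    "length": len(seq),
                }
            )
        for k in range(spec.n_decoy_contigs):
            length = int(rng.integers(300, 801))
            cid = f"{code}.decoy{k + 1:02d}"
            contigs[cid] = _random_nt(rng, length)
            rows.append(
                {
                    "contig_id": cid,
                    "species": name,
                    "is_tdgf": False,
                    "tdgf_id": "",
                    "group_id": "",
                    "base_rate": float(rng.uniform(0.2, 2.0)),
                    "length": length,
                }
            )
    info = pd.DataFrame(rows).set_index("contig_id")
    return Community(contigs=contigs, contig_info=info, species_codes=species_codes)


# Mean sequenced fragment length assumed when deriving effective lengths.
_FRAGMENT_LENGTH = 150
# Arbitrary sequencing depth scalar turning expression into read counts.
_DEPTH = 5e5


def simulate_expression(
    spec: CommunitySpec,
    community: Community,
    catalog: Catalog,
) -> SimulatedExperiment:
    """Simulate per-mouse 16S profiles and RNA-seq abundance tables.

    Each mouse's species composition is a symmetric Dirichlet draw; the 16S
    table reports it exactly (the two data layers share one truth).  For
    RNA-seq mice, a contig's expected expression is
    ``species abundance x base rate x diet multiplier (marker contigs)``
    perturbed by lognormal noise, and TPM follows from expression shares;
    read counts are derived through effective lengths so tables round-trip
    through the quantifier dialect.
    """
    rng = np.random.default_rng(spec.seed + 1)
    species = spec.species
    info = community.contig_info

    mouse_ids: list[str] = []
    diets: list[str] = []
    for diet in ("F", "R", "FR"):  # canonical diet order
        for _ in range(int(spec.mice_per_diet.get(diet, 0))):
            mouse_ids.append(f"m{len(mouse_ids) + 1:02d}")
            diets.append(diet)
    meta = SampleMetadata(
        data=pd.DataFrame(
            {"subject_id": mouse_ids, "diet": diets},
            index=pd.Index(mouse_ids, name="sample_id"),
        )
    )

    abundance = pd.DataFrame(
        rng.dirichlet([spec.dirichlet_alpha] * len(species), size=len(mouse_ids)).T,
        index=species,
        columns=mouse_ids,
    )
    s16 = TaxonAbundanceTable(data=abundance.copy())

    # RNA-seq cohort: n mice per diet, chosen at random
    rnaseq_samples: list[str] = []
    for diet in ("F", "R", "FR"):
        pool = [m for m, d in zip(mouse_ids, diets) if d == diet]
        take = min(spec.n_rnaseq_mice_per_diet, len(pool))
        chosen = rng.choice(len(pool), size=take, replace=False)
        rnaseq_samples.extend(pool[i] for i in sorted(int(c) for c in chosen))

    contig_ids = list(info.index)
    lengths = info["length"].to_numpy(dtype=float)
    eff_lengths = np.maximum(lengths - _FRAGMENT_LENGTH + 1, 1.0)
    base_rates = info["base_rate"].to_numpy(dtype=float)

    tables: dict[str, AbundanceTable] = {}
    for mouse in rnaseq_samples:
        diet = meta.diet_of(mouse)
        expr = np.empty(len(contig_ids))
        for idx, cid in enumerate(contig_ids):
            row = info.loc[cid]
            rate = abundance.loc[row["species"], mouse] * base_rates[idx]
            if row["is_tdgf"]:
                rate *= spec.multiplier(row["group_id"], diet)
            if spec.lognormal_sigma > 0:
                rate *= float(np.exp(rng.normal(0.0, spec.lognormal_sigma)))
            expr[idx] = rate
        tpm = 1e6 * expr / expr.sum()
        counts = expr * eff_lengths
        counts = counts * (_DEPTH / counts.sum())
        tables[mouse] = AbundanceTable(
            sample_id=mouse,
            data=pd.DataFrame(
                {
                    "length": lengths.astype(int),
                    "eff_length": eff_lengths,
                    "est_counts": counts,
                    "tpm": tpm,
                },
                index=pd.Index(contig_ids, name="target_id"),
            ),
        )

    truth = _ground_truth(spec, community, abundance, meta, rnaseq_samples)
    return SimulatedExperiment(
        community=community, tables=tables, s16=s16, metadata=meta, truth=truth
    )


def _ground_truth(
    spec: CommunitySpec,
    community: Community,
    abundance: pd.DataFrame,
    meta: SampleMetadata,
    rnaseq_samples: list[str],
) -> GroundTruth:
    groups = sorted({g for gs in spec.group_assignment.values() for g in gs})
    diets = [d for d in ("F", "R", "FR") if spec.mice_per_diet.get(d, 0) > 0]
    # noise-free expected marker activity per mouse (marker base rate is 1)
    per_mouse = pd.DataFrame(0.0, index=groups, columns=rnaseq_samples)
    for mouse in rnaseq_samples:
        diet = meta.diet_of(mouse)
        for group in groups:
            members = [
                s for s in spec.species if group in spec.group_assignment[s]
            ]
            per_mouse.loc[group, mouse] = spec.multiplier(group, diet) * float(
                sum(abundance.loc[s, mouse] for s in sorted(members))
            )
    shares = per_mouse / per_mouse.sum(axis=0)
    activity = pd.DataFrame(0.0, index=groups, columns=diets)
    share = pd.DataFrame(0.0, index=groups, columns=diets)
    for diet in diets:
        mice = [m for m in rnaseq_samples if meta.diet_of(m) == diet]
        activity[diet] = per_mouse[mice].mean(axis=1)
        share[diet] = shares[mice].mean(axis=1)
    return GroundTruth(
        species_abundance=abundance,
        rnaseq_samples=list(rnaseq_samples),
        contig_info=community.contig_info,
        group_activity=activity,
        group_activity_share=share,
    )


def write_experiment(sim: SimulatedExperiment, out_dir: str | Path) -> None:
    """Write contigs.fasta, abundance/<sample>.tsv, s16.tsv, meta.tsv,
    truth.json — all plain text, byte-stable for a given spec and seed."""
    out = Path(out_dir)
    (out / "abundance").mkdir(parents=True, exist_ok=True)
    with open(out / "contigs.fasta", "w") as fh:
        for cid in sim.community.contigs:
            fh.write(f">{cid}\n")
            seq = sim.community.contigs[cid]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    for sample_id in sorted(sim.tables):
        write_abundance_table(
            sim.tables[sample_id], out / "abundance" / f"{sample_id}.tsv"
        )
    write_16s_table(sim.s16, out / "s16.tsv")
    write_sample_metadata(sim.metadata, out / "meta.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(sim.truth.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
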