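"""Marker catalog: functional groups, their marker proteins, verification.

A functional group (butyrate-producers, acetogens, sulfate-reducers,
mucin-degraders) is a set of community members sharing a metabolic activity.
Each group is quantified through a trait-determining genetic feature (TDGF):
a single marker protein for a key enzyme of the trait's pathway.  Before any
quantification, markers are verified against labeled reference genomes: a
specific marker is found in every in-group genome and in no out-group one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .align import (
    DEFAULT_SCHEME,
    DEFAULT_SCORE_THRESHOLD,
    ScoringScheme,
    best_frame_hit,
    read_fasta,
)

__all__ = [
    "TDGF",
    "FunctionalGroup",
    "Catalog",
    "PresenceMatrix",
    "load_catalog",
    "load_default_catalog",
    "verify_tdgf_presence",
    "specificity_report",
    "self_score",
]

logger = logging.getLogger(__name__)

_PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class TDGF:
    """A trait-determining genetic feature: one marker protein, one group."""

    id: str
    enzyme_name: str
    group_id: str
    protein_seq: str
    ec_number: str | None = None

    def __post_init__(self) -> None:
        if not self.protein_seq:
            raise ValueError(f"TDGF {self.id!r}: empty protein sequence")
        bad = sorted(set(self.protein_seq) - _PROTEIN_ALPHABET)
        if bad:
            raise ValueError(
                f"TDGF {self.id!r}: illegal amino-acid characters {bad}"
            )


@dataclass(frozen=True)
class FunctionalGroup:
    """A set of taxa performing one metabolic activity, with its marker(s).

    A taxon may belong to several groups (e.g. a mucin-degrading
    Bacteroides that also ferments); the shipped default assigns exactly one
    marker per group.
    """

    id: str
    display_name: str
    member_taxa: tuple[str, ...]
    tdgf_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_taxa:
            raise ValueError(f"group {self.id!r}: member_taxa is empty")
        if len(set(self.member_taxa)) != len(self.member_taxa):
            raise ValueError(f"group {self.id!r}: duplicate member taxa")
        if not self.tdgf_ids:
            raise ValueError(f"group {self.id!r}: no TDGF assigned")


@dataclass(frozen=True)
class Catalog:
    tdgfs: dict[str, TDGF]
    groups: dict[str, FunctionalGroup]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("catalog has no groups")
        if not self.tdgfs:
            raise ValueError("catalog has no TDGFs")
        for tdgf in self.tdgfs.values():
            if tdgf.group_id not in self.groups:
                raise ValueError(
                    f"TDGF {tdgf.id!r} references unknown group {tdgf.group_id!r}"
                )
        for group in self.groups.values():
            for tid in group.tdgf_ids:
                if tid not in self.tdgfs:
                    raise ValueError(
                        f"group {group.id!r} references unknown TDGF {tid!r}"
                    )
                if self.tdgfs[tid].group_id != group.id:
                    raise ValueError(
                        f"TDGF {tid!r} is assigned to group "
                        f"{self.tdgfs[tid].group_id!r}, not {group.id!r}"
                    )

    def single_tdgf(self, group_id: str) -> TDGF:
        """The group's single assigned marker; error if it has several."""
        group = self.groups[group_id]
        if len(group.tdgf_ids) != 1:
            raise ValueError(
                f"group {group_id!r} has {len(group.tdgf_ids)} TDGFs; "
                "single-TDGF mode requires exactly one"
            )
        return self.tdgfs[group.tdgf_ids[0]]

    def taxon_groups(self, taxon: str) -> list[str]:
        return [g.id for g in self.groups.values() if taxon in g.member_taxa]

    def restrict(self, tdgf_ids: Iterable[str]) -> "Catalog":
        """Sub-catalog keeping only the named markers and their groups."""
        keep = set(tdgf_ids)
        missing = keep - set(self.tdgfs)
        if missing:
            raise KeyError(f"unknown TDGF ids: {sorted(missing)}")
        tdgfs = {t: self.tdgfs[t] for t in self.tdgfs if t in keep}
        groups = {}
        for gid, group in self.groups.items():
            kept = tuple(t for t in group.tdgf_ids if t in keep)
            if kept:
                groups[gid] = FunctionalGroup(
                    id=group.id,
                    display_name=group.display_name,
                    member_taxa=group.member_taxa,
                    tdgf_ids=kept,
                )
        return Catalog(tdgfs=tdgfs, groups=groups)


def load_catalog(config_path: str | Path, protein_fasta: str | Path) -> Catalog:
    """Load a catalog from a YAML config plus a protein FASTA.

    The config has a ``groups`` list (group_id, display_name, member_taxa)
    and a ``tdgfs`` list (tdgf_id, group_id, enzyme_name, optional ec);
    every declared marker must have a FASTA record of the same id.
    """
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{config_path}: catalog config must be a mapping")
    group_entries = config.get("groups") or []
    tdgf_entries = config.get("tdgfs") or []
    if not group_entries:
        raise ValueError("catalog has no groups")
    if not tdgf_entries:
        raise ValueError("catalog has no TDGFs")

    proteins = read_fasta(protein_fasta)

    group_tdgfs: dict[str, list[str]] = {}
    tdgfs: dict[str, TDGF] = {}
    for entry in tdgf_entries:
        tid = str(entry["tdgf_id"])
        if tid in tdgfs:
            raise ValueError(f"duplicate TDGF id {tid!r} in config")
        if tid not in proteins:
            raise ValueError(
                f"TDGF {tid!r} declared in config but missing from "
                f"protein FASTA {protein_fasta}"
            )
        tdgfs[tid] = TDGF(
            id=tid,
            enzyme_name=str(entry.get("enzyme_name", "")),
            group_id=str(entry["group_id"]),
            protein_seq=proteins[tid],
            ec_number=entry.get("ec"),
        )
        group_tdgfs.setdefault(tdgfs[tid].group_id, []).append(tid)

    groups: dict[str, FunctionalGroup] = {}
    for entry in group_entries:
        gid = str(entry["group_id"])
        if gid in groups:
            raise ValueError(f"duplicate group id {gid!r} in config")
        groups[gid] = FunctionalGroup(
            id=gid,
            display_name=str(entry.get("display_name", gid)),
            member_taxa=tuple(entry["member_taxa"]),
            tdgf_ids=tuple(group_tdgfs.get(gid, ())),
        )
    return Catalog(tdgfs=tdgfs, groups=groups)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("tdgfquant").joinpath("data", name)))


def load_default_catalog(singles_only: bool = True) -> Catalog:
    """The shipped default catalog: 4 groups, 8 markers.

    The protein sequences are synthetic placeholders standing in for the
    real marker enzymes; drop real sequences into a user catalog for actual
    communities.  With ``singles_only`` the catalog is restricted to the four
    per-group analysis markers (acet1, sulfat1, but1, muc2).
    """
    cat = load_catalog(
        _data_path("catalog.yaml"), _data_path("tdgf_proteins.synthetic.fasta")
    )
    if singles_only:
        cat = cat.restrict(["acet1", "sulfat1", "but1", "muc2"])
    return cat


def self_score(protein_seq: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Alignment score of a protein against itself (upper bound for hits)."""
    matrix = scheme.substitution_matrix
    return float(sum(matrix[aa, aa] for aa in protein_seq))


@dataclass
class PresenceMatrix:
    """Best marker-vs-genome alignment scores with a presence call.

    ``scores`` is a genomes x markers DataFrame of best six-frame
    translated-alignment scores; ``present`` is ``scores >= threshold``.
    """

    scores: pd.DataFrame
    threshold: float

    def __post_init__(self) -> None:
        if (self.scores.to_numpy() < 0).any():
            raise ValueError("alignment scores must be non-negative")

    @property
    def present(self) -> pd.DataFrame:
        return self.scores >= self.threshold


def verify_tdgf_presence(
    catalog: Catalog,
    genomes: Mapping[str, Mapping[str, str] | list[str] | str | Path],
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> PresenceMatrix:
    """Score every marker against every labeled genome.

    ``genomes`` maps a genome label to its sequences (a FASTA path, a list
    of nucleotide strings, or an ``{id: seq}`` mapping).  The score for a
    (genome, marker) cell is the best translated local-alignment score over
    all six frames of all of the genome's sequences.
    """
    if not genomes:
        raise ValueError("genome set is empty")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    seqs_by_label: dict[str, list[str]] = {}
    for label, source in genomes.items():
        if isinstance(source, (str, Path)):
            seqs = list(read_fasta(source).values())
        elif isinstance(source, Mapping):
            seqs = list(source.values())
        else:
            seqs = list(source)
        if not seqs:
            raise ValueError(f"genome {label!r} has zero sequences")
        seqs_by_label[label] = seqs

    labels = list(seqs_by_label)
    tdgf_ids = list(catalog.tdgfs)
    scores = pd.DataFrame(0.0, index=labels, columns=tdgf_ids)
    for tid in tdgf_ids:
        query = catalog.tdgfs[tid].protein_seq
        for label in labels:
            best = 0.0
            for seq in seqs_by_label[label]:
                s, _, _, _ = best_frame_hit(query, seq, scheme)
                best = max(best, s)
            scores.loc[label, tid] = best
    return PresenceMatrix(scores=scores, threshold=float(threshold))


def specificity_report(
    presence: PresenceMatrix,
    catalog: Catalog,
    label_to_taxon: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-marker in-group coverage and out-group leakage.

    A marker is *specific* when it is present in every in-group genome
    (coverage 1.0) and absent from every out-group genome.  Genome labels
    are mapped to catalog taxa through ``label_to_taxon`` (identity by
    default); unmapped labels are reported in the log, not fatal.
    ``in_group_coverage`` is NaN when no genome maps into the group.
    """
    label_to_taxon = dict(label_to_taxon or {})
    rows = []
    present = presence.present
    for label in present.index:
        if label not in label_to_taxon:
            label_to_taxon[label] = label
            if not catalog.taxon_groups(label):
                logger.warning(
                    "genome label %r maps to no catalog taxon; treated as out-group",
                    label,
                )
    for tid, tdgf in catalog.tdgfs.items():
        members = set(catalog.groups[tdgf.group_id].member_taxa)
        in_labels = [l for l in present.index if label_to_taxon[l] in members]
        out_labels = [l for l in present.index if label_to_taxon[l] not in members]
        if in_labels:
            coverage = float(present.loc[in_labels, tid].mean())
        else:
            coverage = float("nan")
            logger.warning(
                "TDGF %r: no genomes map to group %r members; coverage undefined",
                tid,
                tdgf.group_id,
            )
        leakage = sorted(l for l in out_labels if bool(present.loc[l, tid]))
        rows.append(
            {
                "tdgf_id": tid,
                "group_id": tdgf.group_id,
                "in_group_coverage": coverage,
                "out_group_hits": ",".join(leakage),
                "specific": bool(coverage == 1.0 and not leakage),
            }
        )
    return pd.DataFrame(rows).set_index("tdgf_id")
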