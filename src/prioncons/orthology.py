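"""Bidirectional best hits (BDBH) ortholog detection and family assembly.

For every reference protein examined, its ortholog in another proteome is the
protein that is the reference's best hit in that proteome while the reference
is reciprocally that protein's best hit back in the whole reference proteome,
both directions passing the E-value threshold (default 0.001).  Families
collect one ortholog per species across a taxonomic level, together with the
pairwise metadata (percent identity, bitscore, self-bitscore) that the
evolutionarily weighted scoring downstream needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .pairwise import (
    AlignParams,
    DEFAULT_PARAMS,
    EncodedProteome,
    PairwiseHit,
    best_hits,
    bit_score,
    local_align,
    sw_raw_score,
)
from .seqio import ProteinRecord, ProteomeSet

log = logging.getLogger(__name__)


@dataclass
class OrthologEntry:
    record: ProteinRecord
    pct_identity: float
    bitscore: float
    self_bitscore: float


@dataclass
class OrthologFamily:
    """A reference protein with its BDBH orthologs at one taxonomic level."""

    reference: ProteinRecord
    orthologs: list[OrthologEntry] = field(default_factory=list)
    level: str = ""
    flagged_empty: bool = False

    @property
    def n(self) -> int:
        return len(self.orthologs)

    def members(self) -> list[ProteinRecord]:
        return [self.reference] + [o.record for o in self.orthologs]


def bdbh(
    reference_proteome: list[ProteinRecord],
    other_proteome: list[ProteinRecord],
    evalue_max: float = 1e-3,
    params: AlignParams = DEFAULT_PARAMS,
    queries: list[str] | None = None,
) -> list[tuple[str, str]]:
    """Reciprocal best-hit pairs (ref_id, other_id) between two proteomes.

    ``queries`` restricts the forward search to a candidate reference list
    (the reciprocal check always runs against the full reference proteome).
    Pairs are returned in reference-proteome order.
    """
    if not reference_proteome or not other_proteome:
        raise ValueError("empty proteome")
    enc_other = EncodedProteome(other_proteome)
    enc_ref = EncodedProteome(reference_proteome)
    fwd = best_hits(reference_proteome, other_proteome, evalue_max, params,
                    queries=queries, _encoded_subjects=enc_other)
    other_by_id = {r.id: r for r in other_proteome}
    # reciprocal check, computed lazily only for the forward best subjects
    back_cache: dict[str, PairwiseHit | None] = {}
    pairs = []
    for ref in reference_proteome:
        hit = fwd.get(ref.id)
        if hit is None:
            continue
        sid = hit.subject_id
        if sid not in back_cache:
            back = best_hits([other_by_id[sid]], reference_proteome, evalue_max,
                             params, _encoded_subjects=enc_ref)
            back_cache[sid] = back.get(sid)
        back_hit = back_cache[sid]
        if back_hit is not None and back_hit.subject_id == ref.id:
            pairs.append((ref.id, sid))
    return pairs


def build_families(
    reference_ids: list[str],
    proteome_set: ProteomeSet,
    reference_species: str,
    level: str,
    evalue_max: float = 1e-3,
    params: AlignParams = DEFAULT_PARAMS,
) -> list[OrthologFamily]:
    """One ortholog family per reference id across the species of a level.

    The reference species itself contributes no ortholog (no self-orthologs);
    each other species contributes at most one protein.  Families with zero
    orthologs are retained but flagged (their weighted score is undefined
    downstream).
    """
    ref_proteome = proteome_set.proteome(reference_species)
    ref_by_id = {r.id: r for r in ref_proteome}
    missing = [i for i in reference_ids if i not in ref_by_id]
    if missing:
        raise ValueError(f"reference ids not in {reference_species}: {missing}")

    families = {
        rid: OrthologFamily(reference=ref_by_id[rid], level=level)
        for rid in reference_ids
    }
    self_bits = {
        rid: bit_score(sw_raw_score(ref_by_id[rid].seq, ref_by_id[rid].seq, params), params)
        for rid in reference_ids
    }
    species = sorted(proteome_set.levels[level] - {reference_species})
    for sp in species:
        other = proteome_set.proteome(sp)
        other_by_id = {r.id: r for r in other}
        for rid, oid in bdbh(ref_proteome, other, evalue_max, params,
                             queries=reference_ids):
            hit = local_align(ref_by_id[rid], other_by_id[oid], params)
            bits = min(hit.bitscore, self_bits[rid])
            if hit.bitscore > self_bits[rid]:
                log.warning("%s vs %s: bitscore exceeds self-bitscore; clamped", rid, oid)
            families[rid].orthologs.append(
                OrthologEntry(
                    record=other_by_id[oid],
                    pct_identity=hit.pct_identity,
                    bitscore=bits,
                    self_bitscore=self_bits[rid],
                )
            )
    for fam in families.values():
        if fam.n == 0:
            fam.flagged_empty = True
            log.warning("family %s/%s has no orthologs", fam.reference.id, level)
    return [families[rid] for rid in reference_ids]


def families_to_frame(families: list[OrthologFamily]) -> pd.DataFrame:
    """Serialize families as a TSV-ready table."""
    rows = []
    for fam in families:
        for o in fam.orthologs:
            rows.append(
                {
                    "ref_id": fam.reference.id,
                    "level": fam.level,
                    "species": o.record.species,
                    "ortholog_id": o.record.id,
                    "pct_identity": o.pct_identity,
                    "bitscore": o.bitscore,
                    "self_bitscore": o.self_bitscore,
                }
            )
        if fam.flagged_empty:
            rows.append(
                {
                    "ref_id": fam.reference.id,
                    "level": fam.level,
                    "species": None,
                    "ortholog_id": None,
                    "pct_identity": None,
                    "bitscore": None,
                    "self_bitscore": None,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["ref_id", "level", "species", "ortholog_id",
                 "pct_identity", "bitscore", "self_bitscore"],
    )
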