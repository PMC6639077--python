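"""Synthetic ortholog families and toy proteomes with planted ground truth.

The generator emulates the evolutionary scenario the analysis assumes: an
ancestral protein made of ordinary-composition flanks around one N/Q-rich
segment, evolved along a three-depth nested star-of-stars tree whose tiers
stand in for the genus, the whole-genome-duplication (WGD) group and the
class.  The N/Q segment substitutes at an independently tunable multiple r of
the flank rate, mirroring the observation that domains with more evidence of
prion-forming ability evolve faster.  Every planted quantity (ortholog pairs,
domain intervals, rate class) is returned as ground truth so each pipeline
stage can be scored without external data.

The reference species sits at the centre of the star (zero-length branch),
so its sequence is the ancestor itself and reference-coordinate truth is
exact.  Substitutions replace residues with draws from a stationary
composition (flanks: average proteome composition; domain: N/Q-enriched);
indels are geometric-length insertions/deletions confined to their segment,
which keeps the true domain interval known exactly in every descendant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrices import ALPHABET
from .prionscore import default_tables
from .seqio import ProteinRecord, ProteomeSet

AA20 = ALPHABET[:20]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Level sizes are cumulative species counts including the reference
    (genus ⊆ wgd ⊆ class).  Depths are expected flank substitutions per site
    accumulated by a species of that tier; with the default flank rate the
    three tiers sit at roughly 90%, 78% and 64% flank identity to the
    reference, spanning the divergence range bidirectional best hits must
    cope with.
    """

    n_genus: int = 2
    n_wgd: int = 4
    n_class: int = 8
    genus_depth: float = 1.0
    wgd_depth: float = 2.5
    class_depth: float = 4.5
    flank_sub_rate: float = 0.10      # substitutions per site per depth unit
    domain_rate_multiplier: float = 1.0
    indel_rate: float = 0.005         # indel events per site per depth unit
    indel_mean_length: float = 2.0
    domain_nq_fraction: float = 0.8
    domain_length: int = 60
    flank_length: int = 60            # each side
    dropout: float = 0.0              # per-species ortholog loss probability
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.n_genus <= self.n_wgd <= self.n_class):
            raise ValueError("level sizes must be nested: genus <= wgd <= class")
        if min(self.flank_sub_rate, self.indel_rate, self.domain_rate_multiplier) < 0:
            raise ValueError("rates must be >= 0")
        if not (0 <= self.domain_nq_fraction <= 1):
            raise ValueError("domain_nq_fraction must be in [0, 1]")

    def species_names(self) -> list[str]:
        return [f"sp{i:02d}" for i in range(self.n_class)]

    @property
    def reference_species(self) -> str:
        return "sp00"

    def levels(self) -> dict[str, set[str]]:
        sp = self.species_names()
        return {
            "genus": set(sp[: self.n_genus]),
            "wgd": set(sp[: self.n_wgd]),
            "class": set(sp),
        }

    def depth_of(self, species: str) -> float:
        i = int(species[2:])
        if i < self.n_genus:
            return self.genus_depth if i > 0 else 0.0
        if i < self.n_wgd:
            return self.wgd_depth
        return self.class_depth


def _flank_composition() -> np.ndarray:
    return default_tables().background_freqs[:20].copy()


def _domain_composition(nq_fraction: float) -> np.ndarray:
    """N/Q take the given mass (55:45 N:Q); the rest follows the proteome
    background renormalized."""
    comp = _flank_composition()
    iN, iQ = AA20.index("N"), AA20.index("Q")
    comp[iN] = comp[iQ] = 0.0
    comp *= (1.0 - nq_fraction) / comp.sum()
    comp[iN] = 0.55 * nq_fraction
    comp[iQ] = 0.45 * nq_fraction
    return comp


def _random_seq(rng: np.random.Generator, length: int, comp: np.ndarray) -> str:
    return "".join(rng.choice(list(AA20), size=length, p=comp))


def _evolve_segment(rng: np.random.Generator, seq: str, p_sub: float,
                    comp: np.ndarray, n_indels: int, mean_len: float) -> str:
    chars = list(seq)
    sub_mask = rng.random(len(chars)) < p_sub
    for i in np.nonzero(sub_mask)[0]:
        chars[i] = AA20[rng.choice(20, p=comp)]
    for _ in range(n_indels):
        if not chars:
            break
        length = int(rng.geometric(1.0 / mean_len))  # geometric, mean = mean_len
        pos = int(rng.integers(0, len(chars)))
        if rng.random() < 0.5:
            ins = [AA20[k] for k in rng.choice(20, size=length, p=comp)]
            chars[pos:pos] = ins
        else:
            del chars[pos : pos + length]
    return "".join(chars)


@dataclass
class FamilySim:
    """One simulated ortholog family with its complete ground truth."""

    ancestor: str
    records: dict[str, ProteinRecord]              # species -> protein
    domain_intervals: dict[str, tuple[int, int]]   # 1-based inclusive
    tree: str                                      # newick
    config: SimConfig
    family_id: str = "F00"


def simulate_family(config: SimConfig, rng: np.random.Generator | None = None,
                    family_id: str = "F00") -> FamilySim:
    """Evolve one ancestor (flank + N/Q domain + flank) across all species.

    Segments evolve independently, so the domain interval of every
    descendant is known exactly.  With all rates zero every species equals
    the ancestor.
    """
    if config.n_class < 1:
        raise ValueError("need at least one species")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    fcomp = _flank_composition()
    dcomp = _domain_composition(config.domain_nq_fraction)
    f1 = _random_seq(rng, config.flank_length, fcomp)
    dom = _random_seq(rng, config.domain_length, dcomp)
    f2 = _random_seq(rng, config.flank_length, fcomp)
    ancestor = f1 + dom + f2

    records: dict[str, ProteinRecord] = {}
    intervals: dict[str, tuple[int, int]] = {}
    for sp in config.species_names():
        d = config.depth_of(sp)
        if d == 0.0:
            nf1, nd, nf2 = f1, dom, f2
        else:
            p_flank = 1.0 - np.exp(-config.flank_sub_rate * d)
            p_dom = 1.0 - np.exp(
                -config.flank_sub_rate * config.domain_rate_multiplier * d
            )

            def n_ind(length):
                lam = config.indel_rate * length * d
                return int(rng.poisson(lam)) if lam > 0 else 0

            nf1 = _evolve_segment(rng, f1, p_flank, fcomp, n_ind(len(f1)),
                                  config.indel_mean_length)
            nd = _evolve_segment(rng, dom, p_dom, dcomp, n_ind(len(dom)),
                                 config.indel_mean_length)
            nf2 = _evolve_segment(rng, f2, p_flank, fcomp, n_ind(len(f2)),
                                  config.indel_mean_length)
        records[sp] = ProteinRecord(
            id=f"{family_id}_{sp}", species=sp, seq=nf1 + nd + nf2
        )
        intervals[sp] = (len(nf1) + 1, len(nf1) + len(nd))

    sp = config.species_names()
    genus = ",".join(f"{s}:{config.genus_depth}" for s in sp[: config.n_genus])
    wgd = ",".join(f"{s}:{config.wgd_depth}" for s in sp[config.n_genus : config.n_wgd])
    cls = ",".join(f"{s}:{config.class_depth}" for s in sp[config.n_wgd :])
    inner = f"({genus})" + (f",{wgd}" if wgd else "")
    tree = f"(({inner}){',' + cls if cls else ''});"
    return FamilySim(ancestor=ancestor, records=records,
                     domain_intervals=intervals, tree=tree,
                     config=config, family_id=family_id)


@dataclass
class ProteomeSimTruth:
    """Ground-truth tables for a simulated proteome set."""

    ortholog_pairs: pd.DataFrame   # ref_id, species, ortholog_id
    domains: pd.DataFrame          # protein_id, species, domain_start/end, has_domain
    families: list[FamilySim] = field(default_factory=list)


def simulate_proteome_set(
    config: SimConfig,
    n_families: int = 30,
    decoy_multiple: int = 5,
    rng: np.random.Generator | None = None,
    domain_length_range: tuple[int, int] | None = None,
    nq_fraction_range: tuple[float, float] | None = None,
) -> tuple[ProteomeSet, ProteomeSimTruth]:
    """Toy proteomes: one ortholog per family per species plus unrelated
    decoys of shuffled (flank) composition.

    Optional per-family ranges for the domain length and N/Q fraction let the
    planted prion-like signal vary across families (needed when downstream
    scores must show spread).  Fully deterministic for a given config seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    families: list[FamilySim] = []
    for k in range(n_families):
        fam_cfg = config
        if domain_length_range is not None:
            fam_cfg = replace(fam_cfg, domain_length=int(
                rng.integers(domain_length_range[0], domain_length_range[1] + 1)))
        if nq_fraction_range is not None:
            fam_cfg = replace(fam_cfg, domain_nq_fraction=float(
                rng.uniform(*nq_fraction_range)))
        families.append(simulate_family(fam_cfg, rng, family_id=f"F{k:03d}"))

    ref = config.reference_species
    proteomes: dict[str, list[ProteinRecord]] = {s: [] for s in config.species_names()}
    pair_rows, dom_rows = [], []
    for fam in families:
        for sp, rec in fam.records.items():
            if sp != ref and config.dropout > 0 and rng.random() < config.dropout:
                continue
            proteomes[sp].append(rec)
            ds, de = fam.domain_intervals[sp]
            dom_rows.append({"protein_id": rec.id, "species": sp,
                             "domain_start": ds, "domain_end": de,
                             "has_domain": True})
            if sp != ref:
                pair_rows.append({"ref_id": fam.records[ref].id, "species": sp,
                                  "ortholog_id": rec.id})
    fam_lengths = [len(fam.records[ref]) for fam in families]
    lo, hi = int(0.7 * min(fam_lengths)), int(1.3 * max(fam_lengths))
    fcomp = _flank_composition()
    for sp in config.species_names():
        for k in range(decoy_multiple * n_families):
            length = int(rng.integers(lo, hi + 1))
            rec = ProteinRecord(id=f"D{k:03d}_{sp}", species=sp,
                                seq=_random_seq(rng, length, fcomp))
            proteomes[sp].append(rec)
            dom_rows.append({"protein_id": rec.id, "species": sp,
                             "domain_start": None, "domain_end": None,
                             "has_domain": False})

    pset = ProteomeSet(proteomes=proteomes, levels=config.levels())
    pset.validate(nested_order=["genus", "wgd", "class"])
    truth = ProteomeSimTruth(
        ortholog_pairs=pd.DataFrame(pair_rows, columns=["ref_id", "species", "ortholog_id"]),
        domains=pd.DataFrame(dom_rows),
        families=families,
    )
    return pset, truth


CATEGORY_MULTIPLIERS = {"KP": 3.0, "PFP": 2.0, "PLP": 1.0}


def simulate_category_families(
    config: SimConfig,
    n_per_group: int = 20,
    multipliers: dict[str, float] = CATEGORY_MULTIPLIERS,
    rng: np.random.Generator | None = None,
) -> dict[str, list[FamilySim]]:
    """Families per category with category-specific domain rate multipliers
    (KP fastest), the synthetic twin of the KP/PFP/PLP set comparison."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out: dict[str, list[FamilySim]] = {}
    for cat, r in multipliers.items():
        cfg = replace(config, domain_rate_multiplier=r)
        out[cat] = [
            simulate_family(cfg, rng, family_id=f"{cat}{k:03d}")
            for k in range(n_per_group)
        ]
    return out
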