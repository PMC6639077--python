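"""Pipeline orchestration: stage order, configuration, manifest, outputs.

Stage order follows the analysis narrative: load/simulate sequences →
ortholog detection → multiple alignment → conservation → prion scoring →
EWPS → comparison statistics.  All results are TSV; a ``manifest.json``
records package version, seed, parameters and per-stage completion, and
re-runs skip completed stages unless forced.

Configuration is a YAML file (or an equivalent dict).  Either a ``simulate``
section (synthetic study) or an ``inputs`` section (real proteome FASTAs, a
level TSV and a protein-set table) must be present.  Precomputed alignments
(``alignments_dir`` with <ref_id>.<level>.afa files) are ingested instead of
running the built-in aligner when provided.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conservation import (
    column_conservation,
    domain_mean_conservation,
    whole_mean_conservation,
)
from .ewps import compute_ewps, ewps_table
from .msa import map_domain_to_columns, progressive_align
from .orthology import OrthologFamily, build_families, families_to_frame
from .pairwise import AlignParams
from .prionscore import PrionScoreParams, load_tables, score_sequence
from .seqio import (
    ProteinSetTable,
    ProteomeSet,
    load_level_table,
    load_protein_sets,
    read_aligned_fasta,
    read_fasta,
    write_aligned_fasta,
    write_fasta,
    write_protein_sets,
)
from .stats import (
    DomainSummary,
    pairwise_test_matrix,
    pearson_r,
    thirds_consistency,
    top_k_table,
)
from .synthetic_data import (
    CATEGORY_MULTIPLIERS,
    SimConfig,
    simulate_family,
)

log = logging.getLogger(__name__)

STAGES = ["sequences", "orthologs", "align", "conserve", "prionscore", "ewps", "stats"]

DEFAULT_PARAMS = {
    "evalue_max": 1e-3,
    "core_length": 60,
    "gap_mask_threshold": 0.5,
    "gap_open": 11,
    "gap_extend": 1,
    "lambda": 0.267,
    "K": 0.041,
    "schemes": ["PC", "BS"],
    "levels": ["genus", "wgd", "class"],
    "top_k": 10,
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    cfg.setdefault("seed", 0)
    cfg.setdefault("params", {})
    merged = dict(DEFAULT_PARAMS)
    merged.update(cfg["params"] or {})
    cfg["params"] = merged
    if "output_dir" not in cfg:
        raise ValueError("config must name an output_dir")
    if ("simulate" not in cfg) == ("inputs" not in cfg):
        raise ValueError("config needs exactly one of 'simulate' or 'inputs'")
    return cfg


def _align_params(p: dict) -> AlignParams:
    return AlignParams(gap_open=p["gap_open"], gap_extend=p["gap_extend"],
                       lambda_=p["lambda"], K=p["K"])


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class Manifest:
    def __init__(self, path: Path, cfg: dict):
        self.path = path
        self.cfg_hash = _config_hash(cfg)
        if path.exists():
            self.data = json.loads(path.read_text())
            if self.data.get("config_hash") != self.cfg_hash:
                log.info("config changed; previous stage results invalidated")
                self.data["stages"] = {}
                self.data["config_hash"] = self.cfg_hash
        else:
            self.data = {
                "package": "prioncons",
                "version": __version__,
                "seed": cfg.get("seed"),
                "params": cfg.get("params"),
                "config_hash": self.cfg_hash,
                "stages": {},
            }

    def done(self, stage: str) -> bool:
        return self.data["stages"].get(stage, {}).get("status") == "complete"

    def mark(self, stage: str, status: str) -> None:
        self.data["stages"][stage] = {
            "status": status,
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


class PipelineState:
    """In-memory handles shared between stages."""

    def __init__(self):
        self.proteome_set: ProteomeSet | None = None
        self.protein_sets: ProteinSetTable | None = None
        self.reference_species: str = ""
        self.reference_ids: list[str] = []
        self.true_domains: dict[str, tuple[int, int]] = {}
        self.families: dict[str, list[OrthologFamily]] = {}   # level -> families
        self.alignments: dict[tuple[str, str], object] = {}   # (ref, level) -> block
        self.cons_summary: pd.DataFrame | None = None
        self.scores: pd.DataFrame | None = None
        self.ewps_results: dict[tuple[str, str], list] = {}   # (level, scheme)
        self.tables: dict[str, pd.DataFrame] = {}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_sequences(cfg: dict, out: Path, state: PipelineState, write: bool = True) -> None:
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        n_per_group = int(sim.pop("n_per_category", 8))
        multipliers = sim.pop("category_multipliers", dict(CATEGORY_MULTIPLIERS))
        sim_cfg = SimConfig(seed=int(cfg["seed"]), **sim)
        rng = np.random.default_rng(sim_cfg.seed)
        proteomes = {s: [] for s in sim_cfg.species_names()}
        entries = {}
        ref = sim_cfg.reference_species
        for cat in sorted(multipliers):
            cat_cfg = replace(sim_cfg, domain_rate_multiplier=float(multipliers[cat]))
            for k in range(n_per_group):
                fam = simulate_family(cat_cfg, rng, family_id=f"{cat}{k:03d}")
                for sp, rec in fam.records.items():
                    proteomes[sp].append(rec)
                ds, de = fam.domain_intervals[ref]
                rid = fam.records[ref].id
                entries[rid] = {"category": cat, "domain_start": ds, "domain_end": de}
                state.true_domains[rid] = (ds, de)
        state.proteome_set = ProteomeSet(proteomes=proteomes, levels=sim_cfg.levels())
        state.proteome_set.validate(nested_order=["genus", "wgd", "class"])
        state.protein_sets = ProteinSetTable(entries=entries)
        state.reference_species = ref
        state.reference_ids = sorted(entries)
        if not write:
            return
        seq_dir = out / "proteomes"
        seq_dir.mkdir(parents=True, exist_ok=True)
        for sp, recs in proteomes.items():
            write_fasta(recs, seq_dir / f"{sp}.fasta")
        levels_df = pd.DataFrame(
            [
                {"species": sp,
                 **{lvl: int(sp in members) for lvl, members in sim_cfg.levels().items()}}
                for sp in sim_cfg.species_names()
            ]
        )
        levels_df.to_csv(out / "levels.tsv", sep="\t", index=False)
        write_protein_sets(state.protein_sets, out / "protein_sets.tsv")
    else:
        inputs = cfg["inputs"]
        pdir = Path(inputs["proteome_dir"])
        fastas = sorted(pdir.glob("*.fasta")) + sorted(pdir.glob("*.fa"))
        if not fastas:
            raise FileNotFoundError(f"no proteome FASTAs in {pdir}")
        proteomes = {f.stem: read_fasta(f, species=f.stem) for f in fastas}
        levels = load_level_table(inputs["level_table"],
                                  known_species=set(proteomes),
                                  nested_order=cfg["params"]["levels"])
        state.proteome_set = ProteomeSet(proteomes=proteomes, levels=levels)
        state.proteome_set.validate()
        state.protein_sets = load_protein_sets(inputs["protein_sets"])
        state.reference_species = inputs["reference_species"]
        state.reference_ids = sorted(state.protein_sets.entries)


def _stage_orthologs(cfg: dict, out: Path, state: PipelineState, write: bool = True) -> None:
    p = cfg["params"]
    odir = out / "orthologs"
    odir.mkdir(exist_ok=True)
    for level in p["levels"]:
        fams = build_families(state.reference_ids, state.proteome_set,
                              state.reference_species, level,
                              evalue_max=p["evalue_max"],
                              params=_align_params(p))
        state.families[level] = fams
        if write:
            families_to_frame(fams).to_csv(odir / f"{level}.tsv", sep="\t", index=False)
            for fam in fams:
                write_fasta(fam.members(), odir / f"{fam.reference.id}.{level}.fasta")


def _stage_align(cfg: dict, out: Path, state: PipelineState, write: bool = True) -> None:
    adir = out / "alignments"
    adir.mkdir(exist_ok=True)
    ext_dir = Path(cfg.get("inputs", {}).get("alignments_dir", "")) if cfg.get("inputs") else None
    p = cfg["params"]
    for level, fams in state.families.items():
        for fam in fams:
            name = f"{fam.reference.id}.{level}.afa"
            if ext_dir and (ext_dir / name).exists():
                block = read_aligned_fasta(ext_dir / name)
            else:
                block = progressive_align(fam, _align_params(p))
            state.alignments[(fam.reference.id, level)] = block
            if write:
                write_aligned_fasta(block, adir / name)


def _domain_interval(state: PipelineState, cfg: dict, rid: str) -> tuple[int, int] | None:
    """Experimentally determined boundaries if present, else the predicted
    prion-domain interval of the reference sequence."""
    dom = state.protein_sets.domain(rid)
    if dom is not None:
        return dom
    ref = next(r for r in state.proteome_set.proteome(state.reference_species)
               if r.id == rid)
    tables = _tables(cfg)
    res = score_sequence(ref, tables,
                         PrionScoreParams(core_length=cfg["params"]["core_length"]))
    return res.domain_interval


def _tables(cfg: dict):
    t = cfg.get("tables", {})
    return load_tables(t.get("prion"), t.get("background"))


def _stage_conserve(cfg: dict, out: Path, state: PipelineState, write: bool = True) -> None:
    p = cfg["params"]
    cdir = out / "conservation"
    cdir.mkdir(exist_ok=True)
    rows = []
    for level, fams in state.families.items():
        per_col_rows = []
        for fam in fams:
            rid = fam.reference.id
            block = state.alignments[(rid, level)]
            if block.nrows < 2:
                rows.append({"ref_id": rid, "level": level, "n_rows": block.nrows,
                             "domain_mean": np.nan, "domain_sd": np.nan,
                             "whole_mean": np.nan, "whole_sd": np.nan,
                             "flag": "no_orthologs"})
                continue
            prof = column_conservation(block, p["gap_mask_threshold"])
            dom = _domain_interval(state, cfg, rid)
            if dom is None:
                dmean = dsd = np.nan
                flag = "no_domain"
            else:
                cols = map_domain_to_columns(block, rid, dom)
                dmean, dsd = domain_mean_conservation(prof, cols)
                flag = "" if not np.isnan(dmean) else "domain_masked"
            wmean, wsd = whole_mean_conservation(prof)
            rows.append({"ref_id": rid, "level": level, "n_rows": block.nrows,
                         "domain_mean": dmean, "domain_sd": dsd,
                         "whole_mean": wmean, "whole_sd": wsd, "flag": flag})
            for c in range(prof.ncols):
                per_col_rows.append({
                    "ref_id": rid, "column": c + 1,
                    "raw": prof.raw_scores[c],
                    "normalized": prof.column_scores[c],
                    "masked": bool(prof.masked_columns[c]),
                })
        if write:
            pd.DataFrame(per_col_rows).to_csv(cdir / f"{level}_columns.tsv",
                                              sep="\t", index=False)
    state.cons_summary = pd.DataFrame(rows)
    if write:
        state.cons_summary.to_csv(cdir / "domain_summary.tsv", sep="\t", index=False)


def _stage_prionscore(cfg: dict, out: Path, state: PipelineState, write: bool = True) -> None:
    p = cfg["params"]
    tables = _tables(cfg)
    sparams = PrionScoreParams(core_length=p["core_length"])
    rows = []
    scored: set[str] = set()
    # reference proteins plus every family member across levels
    targets = []
    for rid in state.reference_ids:
        targets.append(next(r for r in state.proteome_set.proteome(state.reference_species)
                            if r.id == rid))
    for fams in state.families.values():
        for fam in fams:
            targets.extend(o.record for o in fam.orthologs)
    for rec in targets:
        if rec.id in scored:
            continue
        scored.add(rec.id)
        res = score_sequence(rec, tables, sparams)
        rows.append({"id": rec.id, "species": rec.species,
                     "prd_score": res.prd_score, "llr": res.llr,
                     "domain_start": res.domain_interval[0] if res.domain_interval else None,
                     "domain_end": res.domain_interval[1] if res.domain_interval else None})
    state.scores = pd.DataFrame(rows)
    if write:
        sdir = out / "prionscore"
        sdir.mkdir(exist_ok=True)
        state.scores.to_csv(sdir / "scores.tsv", sep="\t", index=False)


def _stage_ewps(cfg: dict, out: Path, state: PipelineState, write: bool = True) -> None:
    p = cfg["params"]
    edir = out / "ewps"
    edir.mkdir(exist_ok=True)
    score_of = dict(zip(state.scores["id"], state.scores["prd_score"]))
    cats = {rid: state.protein_sets.category(rid) for rid in state.reference_ids}
    for level, fams in state.families.items():
        for scheme in p["schemes"]:
            results = []
            for fam in fams:
                ortholog_scores = [score_of[o.record.id] for o in fam.orthologs]
                results.append(compute_ewps(fam, ortholog_scores, scheme))
            state.ewps_results[(level, scheme)] = results
            if write:
                ewps_table(results, cats).to_csv(
                    edir / f"{level}_{scheme.lower()}.tsv", sep="\t", index=False)


def _stage_stats(cfg: dict, out: Path, state: PipelineState, write: bool = True) -> None:
    p = cfg["params"]
    sdir = out / "stats"
    sdir.mkdir(exist_ok=True)
    score_of = dict(zip(state.scores["id"], state.scores["prd_score"]))
    cons = state.cons_summary.set_index(["ref_id", "level"])

    summaries: dict[str, list[DomainSummary]] = {}
    for level in p["levels"]:
        ew = {s: {r.ref_id: r for r in state.ewps_results[(level, s)]}
              for s in p["schemes"]}
        lvl_sums = []
        for rid in state.reference_ids:
            c = cons.loc[(rid, level)]
            pc = ew.get("PC", {}).get(rid)
            bs = ew.get("BS", {}).get(rid)
            lvl_sums.append(DomainSummary(
                ref_id=rid,
                category=state.protein_sets.category(rid),
                level=level,
                domain_mean_cons=float(c["domain_mean"]),
                whole_mean_cons=float(c["whole_mean"]),
                scps=float(score_of[rid]),
                ewps_pc=float(pc.ewps) if pc and not pc.undefined else np.nan,
                ewps_bs=float(bs.ewps) if bs and not bs.undefined else np.nan,
                undefined=bool(c["flag"]) or (pc is not None and pc.undefined),
            ))
        summaries[level] = lvl_sums

    # set-vs-set conservation tests (domain and whole-sequence), per level
    test_rows = []
    for level, lvl_sums in summaries.items():
        for field in ("domain_mean_cons", "whole_mean_cons"):
            groups = {}
            for cat in ("KP", "PFP", "PLP"):
                vals = [getattr(s, field) for s in lvl_sums
                        if s.category == cat and not np.isnan(getattr(s, field))]
                if len(vals) >= 2:
                    groups[cat] = vals
            if len(groups) >= 2:
                df = pairwise_test_matrix(groups, "welch")
                df.insert(0, "level", level)
                df.insert(1, "field", field)
                test_rows.append(df)
    if test_rows and write:
        pd.concat(test_rows).to_csv(sdir / "conservation_tests.tsv", sep="\t", index=False)

    # EWPS / SCPS set comparisons (Mann-Whitney)
    mwu_rows = []
    for level, lvl_sums in summaries.items():
        for field in ("ewps_pc", "scps"):
            groups = {}
            for cat in ("KP", "PFP", "PLP"):
                vals = [getattr(s, field) for s in lvl_sums
                        if s.category == cat and not np.isnan(getattr(s, field))]
                if vals:
                    groups[cat] = vals
            if len(groups) >= 2:
                df = pairwise_test_matrix(groups, "mwu")
                df.insert(0, "level", level)
                df.insert(1, "field", field)
                mwu_rows.append(df)
    if mwu_rows and write:
        pd.concat(mwu_rows).to_csv(sdir / "ewps_tests.tsv", sep="\t", index=False)

    # correlations per set and level: EWPS vs SCPS, EWPS vs conservation,
    # SCPS vs conservation
    corr_rows = []
    for level, lvl_sums in summaries.items():
        sets = {"PFP": [s for s in lvl_sums if s.category in ("KP", "PFP")],
                "PLP": [s for s in lvl_sums if s.category == "PLP"]}
        for set_name, members in sets.items():
            if len(members) < 3:
                continue
            for xf, yf, label in (
                ("ewps_pc", "scps", "ewps_vs_scps"),
                ("ewps_pc", "domain_mean_cons", "ewps_vs_cons"),
                ("scps", "domain_mean_cons", "scps_vs_cons"),
            ):
                x = [getattr(s, xf) for s in members]
                y = [getattr(s, yf) for s in members]
                try:
                    r, pv = pearson_r(x, y)
                except ValueError:
                    continue
                corr_rows.append({"level": level, "set": set_name,
                                  "pair": label, "r": r, "p": pv})
    if write:
        pd.DataFrame(corr_rows).to_csv(sdir / "correlations.tsv", sep="\t", index=False)

    # thirds consistency of domain conservation across levels
    by_protein: dict[str, dict[str, float]] = {}
    for level, lvl_sums in summaries.items():
        for s in lvl_sums:
            if not np.isnan(s.domain_mean_cons):
                by_protein.setdefault(s.ref_id, {})[level] = s.domain_mean_cons
    complete = {rid: v for rid, v in by_protein.items() if len(v) == len(p["levels"])}
    if len(complete) >= 3:
        thirds = thirds_consistency(complete)
        if write:
            thirds.to_csv(sdir / "thirds.tsv", sep="\t", index=False)
        state.tables["thirds"] = thirds

    # top-k ranking tables at the broadest level
    broad = p["levels"][-1]
    for key in ("ewps_pc", "ewps_bs", "domain_mean_cons"):
        tbl = top_k_table(summaries[broad], key, p["top_k"])
        if write:
            tbl.to_csv(sdir / f"top{p['top_k']}_{key}.tsv", sep="\t", index=False)
        state.tables[f"top_{key}"] = tbl
    state.tables["summaries"] = pd.DataFrame(
        [vars(s) for lvl_sums in summaries.values() for s in lvl_sums]
    )
    if write:
        state.tables["summaries"].to_csv(sdir / "domain_summaries.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "sequences": _stage_sequences,
    "orthologs": _stage_orthologs,
    "align": _stage_align,
    "conserve": _stage_conserve,
    "prionscore": _stage_prionscore,
    "ewps": _stage_ewps,
    "stats": _stage_stats,
}


def run_pipeline(config, force: bool = False, upto: str | None = None) -> PipelineState:
    """Execute the stages in order; returns the final in-memory state.

    Stage outputs land under ``output_dir``; the manifest marks completion.
    On failure the completed stages' outputs are preserved and the manifest
    records the failure point.
    """
    cfg = load_config(config)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out / "manifest.json", cfg)
    state = PipelineState()
    stages = STAGES[: STAGES.index(upto) + 1] if upto else STAGES
    for stage in stages:
        t0 = time.time()
        # completed stages are skipped: their outputs stay untouched, but the
        # (deterministic) in-memory state later stages need is recomputed
        write = force or not manifest.done(stage)
        try:
            _STAGE_FUNCS[stage](cfg, out, state, write=write)
        except Exception:
            manifest.mark(stage, "failed")
            raise
        manifest.mark(stage, "complete")
        log.info("stage %-10s %s (%.1fs)", stage,
                 "complete" if write else "skipped", time.time() - t0)
    return state
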