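"""End-to-end orchestration of the comparative-genomics stages.

Stage order: simulate -> bin -> rbh -> divergence -> classes -> plasmid-test.
Every stage writes tab-separated tables (metadata lines prefixed with '#')
into the output directory; the run ends with a manifest listing each file
and its checksum, plus a log of parameters and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import binning, divergence, homology, inventory, plasmid, simdata
from .align import family_alignment

logger = logging.getLogger("baeocomp")


@dataclass
class RunConfig:
    out_dir: str = "baeocomp_run"
    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate", "bin", "rbh", "divergence", "classes", "plasmid-test",
    )
    # simulator
    n_families: int = 60
    codon_length: int = 150
    omega: float = 0.2
    # thresholds
    coverage_min: float = 70.0
    identity_margin: float = 10.0
    score_min: float = 50.0
    window_syn_sites: float = 500.0
    plasmid_threshold: float = 0.7

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, meta: dict | None = None, index=False):
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def _family_of(gene_id: str) -> int:
    return int(gene_id.split("_")[0][3:])


def _copy_of(gene_id: str) -> int:
    return int(gene_id.split("|")[0].split("_")[1])


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("run config: %s", asdict(config))

    written: list[Path] = []
    state: dict = {}
    try:
        for stage in config.stages:
            logger.info("stage %s", stage)
            written += _STAGES[stage](config, out, state)
    except Exception:
        logger.exception("stage failed")
        _write_manifest(out, written, partial=True)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    written.append(log_path)
    manifest = _write_manifest(out, written, partial=False)
    logger.info("done in %.1f s", time.time() - t0)
    return manifest


def _write_manifest(out: Path, files: list[Path], partial: bool) -> dict:
    manifest = {
        "partial": partial,
        "files": [
            {"path": str(p.relative_to(out)), "sha256": _checksum(p), "bytes": p.stat().st_size}
            for p in files
            if p.exists()
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> list[Path]:
    sim_cfg = simdata.SimConfig(
        n_families=config.n_families,
        codon_length=config.codon_length,
        omega=config.omega,
        seed=config.seed,
    )
    strain_sets, truth = simdata.simulate_strain_set(sim_cfg)
    fix_dir = out / "fixture"
    simdata.write_fixture(strain_sets, truth, fix_dir)
    state["strain_sets"], state["truth"] = strain_sets, truth
    files = sorted(fix_dir.iterdir())

    profiles, binner2, contig_truth = simdata.simulate_contig_profiles(seed=config.seed)
    state["profiles"], state["binner2"] = profiles, binner2
    hit_rows, meta_rows = [], []
    for p in profiles:
        meta_rows.append(dict(contig_id=p.contig_id, length_bp=p.length_bp,
                              coverage=round(p.coverage, 2)))
        for grp, ident, score in p.hits:
            hit_rows.append(dict(contig_id=p.contig_id, taxon_group=grp,
                                 percent_identity=ident, score=score))
    _write_tsv(pd.DataFrame(hit_rows), fix_dir / "contig_hits.tsv")
    _write_tsv(pd.DataFrame(meta_rows), fix_dir / "contigs.tsv")
    _write_tsv(
        pd.DataFrame(
            [dict(contig_id=k, label=v) for k, v in binner2.items()]
        ),
        fix_dir / "binner2.tsv",
    )
    files += [fix_dir / "contig_hits.tsv", fix_dir / "contigs.tsv", fix_dir / "binner2.tsv"]
    return files


def _stage_bin(config: RunConfig, out: Path, state: dict) -> list[Path]:
    profiles = state.get("profiles")
    if profiles is None:
        profiles = binning.load_hit_profiles(
            out / "fixture" / "contig_hits.tsv", out / "fixture" / "contigs.tsv"
        )
        binner2 = dict(
            pd.read_csv(out / "fixture" / "binner2.tsv", sep="\t").values
        )
    else:
        binner2 = state["binner2"]
    decisions = [
        binning.classify_contig(p, config.coverage_min, config.identity_margin)
        for p in profiles
    ]
    result = binning.congruence_filter(decisions, binner2)
    logger.info(
        "binning: %d retained, congruence %.3f, %d excluded",
        len(result.retained), result.congruence_fraction, len(result.excluded),
    )
    dec_path = out / "bin_decisions.tsv"
    _write_tsv(
        binning.decisions_to_frame(result.decisions),
        dec_path,
        meta={"congruence_fraction": f"{result.congruence_fraction:.4f}"},
    )
    retained_path = out / "retained_contigs.txt"
    retained_path.write_text("\n".join(result.retained) + "\n")
    state["bin_result"] = result
    return [dec_path, retained_path]


def _require_sim(config: RunConfig, state: dict):
    if "strain_sets" not in state:
        raise RuntimeError("the simulate stage must run first in this pipeline")
    return state["strain_sets"], state["truth"]


def _stage_rbh(config: RunConfig, out: Path, state: dict) -> list[Path]:
    strain_sets, truth = _require_sim(config, state)
    strains = list(strain_sets)
    focal = strains[0]
    subject_sets = {s: strain_sets[s] for s in strains[1:]}
    calls = homology.classify_all(
        strain_sets[focal], subject_sets, score_threshold=config.score_min
    )
    state["calls"], state["focal"] = calls, focal
    calls_path = out / "rbh_calls.tsv"
    _write_tsv(homology.calls_to_frame(calls), calls_path,
               meta={"focal_strain": focal, "score_min": config.score_min})
    summary = homology.summarize_homology(
        calls, total_query_genes=len(strain_sets[focal]), strains=strains[1:]
    )
    summary_path = out / "homology_summary.tsv"
    _write_tsv(summary, summary_path, index=True)
    n_core = len(homology.union_no_similarity(calls))
    logger.info("rbh: %d focal genes, %d with no similarity anywhere",
                len(strain_sets[focal]), n_core)
    return [calls_path, summary_path]


def _collect_families(strain_sets, strains):
    """family -> {strain: primary-copy GeneRecord} using copy-1 genes only."""
    fams: dict[int, dict[str, object]] = {}
    for strain in strains:
        for rec in strain_sets[strain]:
            if _copy_of(rec.gene_id) != 1:
                continue
            fams.setdefault(_family_of(rec.gene_id), {})[strain] = rec
    return fams


def _stage_divergence(config: RunConfig, out: Path, state: dict) -> list[Path]:
    strain_sets, truth = _require_sim(config, state)
    strains = list(strain_sets)
    focal = strains[0]
    fams = _collect_families(strain_sets, strains)

    all_fams = {f: m for f, m in fams.items() if len(m) == len(strains)}
    alignments = [
        family_alignment(list(m.values()), name=f"fam{f}")
        for f, m in sorted(all_fams.items())
    ]
    # rename records to strain ids so alignments share taxa
    for aln, (f, m) in zip(alignments, sorted(all_fams.items())):
        aln.records = [(s, seq) for s, (_gid, seq) in zip(m.keys(), aln.records)]
    kept, dropped = divergence.filter_multiple_of_three(alignments)
    logger.info("divergence: %d all-strain families, %d frame-intact, %d dropped",
                len(alignments), len(kept), len(dropped))
    files = []
    div_rows = []
    windows_rows = []
    tests = {}
    if kept:
        concat = divergence.concatenate(kept)
        for other in strains[1:]:
            div = divergence.ng86(concat.sequence(focal), concat.sequence(other))
            div_rows.append(dict(strain=other, scope="all",
                                 **divergence.divergence_to_dict(div)))
            import warnings as _warnings
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                all_series = divergence.windowed_ks(
                    concat, focal, other, config.window_syn_sites, source="all"
                )
            for idx, s, ks in all_series.windows:
                windows_rows.append(dict(strain=other, scope="all", window=idx,
                                         syn_sites=round(s, 2), Ks=ks))
            # pair-restricted families for this strain
            pair_fams = {
                f: m for f, m in fams.items()
                if set(m) == {focal, other}
            }
            if pair_fams:
                pair_alns = []
                for f, m in sorted(pair_fams.items()):
                    aln = family_alignment([m[focal], m[other]], name=f"fam{f}")
                    aln.records = [(focal, aln.records[0][1]), (other, aln.records[1][1])]
                    pair_alns.append(aln)
                pair_kept, _ = divergence.filter_multiple_of_three(pair_alns)
                if pair_kept:
                    pair_concat = divergence.concatenate(pair_kept)
                    pair_div = divergence.ng86(
                        pair_concat.sequence(focal), pair_concat.sequence(other)
                    )
                    div_rows.append(dict(strain=other, scope="pair",
                                         **divergence.divergence_to_dict(pair_div)))
                    with _warnings.catch_warnings():
                        _warnings.simplefilter("ignore")
                        pair_series = divergence.windowed_ks(
                            pair_concat, focal, other, config.window_syn_sites,
                            source=f"pair:{other}",
                        )
                    for idx, s, ks in pair_series.windows:
                        windows_rows.append(dict(strain=other, scope="pair",
                                                 window=idx, syn_sites=round(s, 2),
                                                 Ks=ks))
                    if all_series.windows and pair_series.windows:
                        u, p = divergence.mann_whitney(
                            all_series.ks_values, pair_series.ks_values
                        )
                        tests[other] = dict(U=u, p_two_sided=p,
                                            n_all=len(all_series.windows),
                                            n_pair=len(pair_series.windows))
    div_path = out / "divergence.tsv"
    _write_tsv(pd.DataFrame(div_rows), div_path)
    win_path = out / "ks_windows.tsv"
    _write_tsv(pd.DataFrame(windows_rows), win_path)
    tests_path = out / "hgt_tests.json"
    tests_path.write_text(json.dumps(tests, indent=2))
    files += [div_path, win_path, tests_path]
    state["fams"] = fams
    return files


def _stage_classes(config: RunConfig, out: Path, state: dict) -> list[Path]:
    strain_sets, truth = _require_sim(config, state)
    calls = state["calls"]
    focal = state["focal"]
    matrix = inventory.build_matrix(calls, strain_sets[focal])
    state["matrix"] = matrix
    sizes_path = out / "class_sizes.tsv"
    _write_tsv(inventory.class_sizes(matrix).to_frame(), sizes_path, index=True)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        profile = inventory.class_category_profile(matrix)
    prof_path = out / "class_category_profile.tsv"
    _write_tsv(profile, prof_path, index=True)
    freq_path = out / "strain_absence_frequency.tsv"
    _write_tsv(inventory.strain_absence_frequency(matrix), freq_path, index=True)
    return [sizes_path, prof_path, freq_path]


def _stage_plasmid(config: RunConfig, out: Path, state: dict) -> list[Path]:
    strain_sets, truth = _require_sim(config, state)
    if "matrix" not in state:
        raise RuntimeError("the classes stage must run before plasmid-test")
    matrix = state["matrix"]
    strains = list(strain_sets)
    focal = strains[0]
    fams = state.get("fams") or _collect_families(strain_sets, strains)

    probs = truth.genes.rename(columns={"strain": "gene_strain"})[
        ["gene_id", "chromosome_prob", "plasmid_prob"]
    ]
    sweep = plasmid.threshold_sweep(probs)
    sweep_path = out / "plasmid_threshold_sweep.tsv"
    _write_tsv(sweep, sweep_path)

    calls = plasmid.apply_threshold(probs, config.plasmid_threshold)
    compartments = {c.entity_id: c.effective_label for c in calls}

    n_comp = len(matrix.strains)
    pair_sets: dict[str, set[str]] = {}
    core_sets: dict[str, set[str]] = {}
    core_fams = [
        _family_of(g) for g in matrix.genes_in_class(0)
        if _copy_of(g) == 1
    ]
    for other in matrix.strains:
        pair_genes = set()
        for g in matrix.genes_in_class(n_comp - 1):
            if _copy_of(g) != 1:
                continue
            present = matrix.presence.loc[g]
            if present[other]:
                fam = _family_of(g)
                partner = fams.get(fam, {}).get(other)
                if partner is not None:
                    pair_genes.add(partner.gene_id)
        core = {
            fams[f][other].gene_id
            for f in core_fams
            if other in fams.get(f, {})
        }
        pair_sets[other] = pair_genes - core
        core_sets[other] = core
    results = {}
    rows = []
    for other in matrix.strains:
        if not pair_sets[other] or not core_sets[other]:
            continue
        res = plasmid.enrichment_pipeline(
            {other: pair_sets[other]}, {other: core_sets[other]}, compartments
        )[other]
        table, fisher = res
        results[other] = dict(
            a=table.a, b=table.b, c=table.c, d=table.d,
            p_two_sided=fisher.p_two_sided,
            odds_ratio=None if fisher.odds_ratio_infinite else fisher.odds_ratio,
        )
        rows.append(dict(strain=other, pair_plasmid=table.a, pair_chromosome=table.b,
                         core_plasmid=table.c, core_chromosome=table.d,
                         p_two_sided=fisher.p_two_sided))
    enr_path = out / "plasmid_enrichment.tsv"
    _write_tsv(pd.DataFrame(rows), enr_path)
    enr_json = out / "plasmid_enrichment.json"
    enr_json.write_text(json.dumps(results, indent=2))
    return [sweep_path, enr_path, enr_json]


_STAGES = {
    "simulate": _stage_simulate,
    "bin": _stage_bin,
    "rbh": _stage_rbh,
    "divergence": _stage_divergence,
    "classes": _stage_classes,
    "plasmid-test": _stage_plasmid,
}
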