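"""End-to-end orchestration: simulate -> align -> assemble -> localize -> stats.

A run is fully determined by its :class:`RunConfig` (seed mandatory); the
manifest it returns records parameter echoes, per-stage counts, the
haplotype group tables, the localized NAHR events with truth comparison,
the statistical summaries, and a content hash that is stable across
reruns with the same seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import map_io
from .align import AlignParams, compute_qc
from .assembly import chain_haplotypes, detect_inversion, group_haplotypes
from .nahr import NAHRLocalizationError, localize_trio
from .simulate import (
    DEFAULT_ANNOTATIONS,
    SimParams,
    Trio,
    default_catalog,
    dense_catalog,
    simulate_molecules,
    simulate_trio,
)
from .stats import fisher_2x2, origin_ratio, proportion_summary
from .types import AnnotationInterval, LabelMap

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_end_to_end", "report", "default_annotations", "noisy_contig"]


def default_annotations() -> list[AnnotationInterval]:
    return [
        AnnotationInterval(name, lo, hi, ref)
        for name, (lo, hi, ref) in DEFAULT_ANNOTATIONS.items()
    ]


@dataclass(frozen=True)
class RunConfig:
    """Reproducible-run description; every field has a desk-scale default."""

    seed: int
    n_families: int = 5
    coverage: float = 50.0
    catalog: str = "default"  # "default" | "dense"
    origin_female_prob: float = 19 / 30
    sim: SimParams = field(default_factory=SimParams)
    aln: AlignParams = field(default_factory=AlignParams)
    # consensus-level noise applied to the proband deletion contig before
    # localization (assembled consensus maps are far cleaner than molecules)
    contig_jitter_bp: float = 300.0
    contig_miss_rate: float = 0.02
    contig_extra_rate: float = 0.01
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        sim = SimParams(**raw.pop("sim", {}))
        aln = AlignParams(**raw.pop("aln", {}))
        return cls(sim=sim, aln=aln, **raw)


def noisy_contig(contig: LabelMap, rng, jitter_bp: float, miss_rate: float,
                 extra_rate: float) -> LabelMap:
    """Consensus-map error model: small jitter, rare missing/extra labels."""
    pos = contig.positions.astype(float)
    keep = rng.random(pos.size) >= miss_rate
    pos = pos[keep] + rng.normal(0.0, jitter_bp, int(keep.sum()))
    n_extra = rng.poisson(extra_rate * contig.n_labels)
    if n_extra:
        pos = np.concatenate([pos, rng.uniform(1, contig.length_bp, n_extra)])
    pos = np.clip(np.sort(pos), 1, contig.length_bp)
    if pos.size > 1:
        pos = pos[np.concatenate([[True], np.diff(pos) > 1])]
    return LabelMap(contig.map_id + ".noisy", contig.length_bp, pos, dict(contig.meta))


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full pipeline; returns (and optionally writes) the manifest."""
    catalog = dense_catalog() if config.catalog == "dense" else default_catalog()
    ss = np.random.SeedSequence(config.seed)
    sim = dataclasses.replace(config.sim, coverage=config.coverage)

    manifest: dict = {
        "config": {
            "seed": config.seed,
            "n_families": config.n_families,
            "coverage": config.coverage,
            "catalog": config.catalog,
            "sim": dataclasses.asdict(sim),
            "aln": dataclasses.asdict(config.aln),
        },
        "stages": {},
        "failure_stage": None,
    }

    try:
        trios = _stage_simulate(config, catalog, sim, ss, manifest)
        calls, mol_counts, qc = _stage_assemble(config, trios, sim, ss, manifest)
        events = _stage_localize(config, trios, ss, manifest)
        _stage_stats(trios, events, manifest)
    except Exception as exc:  # manifest preserves partial outputs
        logger.exception("pipeline stage failed")
        manifest["failure_stage"] = manifest.get("_current_stage", "unknown")
        manifest["error"] = f"{type(exc).__name__}: {exc}"
    manifest.pop("_current_stage", None)
    manifest["manifest_hash"] = _hash_manifest(manifest)
    if config.outdir:
        _write_artifacts(config, manifest)
    return manifest


def _stage_simulate(config, catalog, sim, ss, manifest) -> list[Trio]:
    manifest["_current_stage"] = "simulate"
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_families)]
    trios = [
        simulate_trio(
            catalog, sim, seed=seeds[i], family_id=f"fam{i:03d}",
            origin_female_prob=config.origin_female_prob,
        )
        for i in range(config.n_families)
    ]
    manifest["stages"]["simulate"] = {
        "n_families": len(trios),
        "origin_counts": {
            "mother": sum(t.truth.parent_of_origin == "mother" for t in trios),
            "father": sum(t.truth.parent_of_origin == "father" for t in trios),
        },
    }
    return trios


def _stage_assemble(config, trios, sim, ss, manifest):
    manifest["_current_stage"] = "assemble"
    all_calls = []
    totals = {"assigned": 0, "ambiguous": 0, "filtered": 0, "total": 0}
    qc_sample = None
    mol_seed_root = ss.spawn(1)[0]
    seeds = iter(
        int(s.generate_state(1)[0] % (2**31))
        for s in mol_seed_root.spawn(max(len(trios), 1) * 4 + 4)
    )
    for trio in trios:
        origin = trio.truth.parent_of_origin
        for parent_name in ("mother", "father"):
            parent = getattr(trio, parent_name)
            role = "parent-of-origin" if parent_name == origin else "NAHR-negative"
            for locus in ("LCR22A", "LCR22D"):
                pair = list(parent[locus])
                mols = simulate_molecules(pair, sim, seed=next(seeds))
                calls, rep = chain_haplotypes(mols, pair, config.aln)
                for c in calls:
                    c.role = role
                all_calls.extend(calls)
                for k in totals:
                    totals[k] += rep[k]
                if qc_sample is None:
                    qc_sample = compute_qc(mols, [h.labelmap for h in pair], config.aln)
    manifest["stages"]["assemble"] = {
        "molecules": totals,
        "haplotypes_complete": sum(c.is_complete for c in all_calls),
        "haplotypes_incomplete": sum(not c.is_complete for c in all_calls),
    }
    if qc_sample is not None:
        manifest["stages"]["assemble"]["qc"] = {
            "fp_rate": qc_sample.fp_rate,
            "fn_rate": qc_sample.fn_rate,
            "labels_per_100kbp": qc_sample.labels_per_100kbp,
            "flags": list(qc_sample.flags),
        }
    for gran in ("features", "labels"):
        table = group_haplotypes([c for c in all_calls if c.haplotype.locus == "LCR22A"], gran)
        manifest["stages"][f"groups_A_{gran}"] = {
            str(k): int(v) for k, v in table["count"].items()
        } if len(table) else {}
    table = group_haplotypes([c for c in all_calls if c.haplotype.locus == "LCR22D"], "features")
    manifest["stages"]["groups_D_features"] = (
        {str(k): int(v) for k, v in table["count"].items()} if len(table) else {}
    )
    return all_calls, totals, qc_sample


def _stage_localize(config, trios, ss, manifest):
    manifest["_current_stage"] = "localize"
    annotations = default_annotations()
    rng = np.random.default_rng(ss.spawn(1)[0])
    events = []
    failed = 0
    for trio in trios:
        contig = noisy_contig(
            trio.proband_deletion, rng, config.contig_jitter_bp,
            config.contig_miss_rate, config.contig_extra_rate,
        )
        try:
            ev = localize_trio(trio, annotations, config.aln, contig=contig)
        except NAHRLocalizationError as exc:
            logger.warning("%s: %s", trio.family_id, exc)
            failed += 1
            continue
        lo, hi = ev.ambiguous_interval
        events.append(
            {
                "family_id": ev.family_id,
                "parent_of_origin": ev.parent_of_origin,
                "interval_abs": list(ev.ambiguous_interval_abs),
                "width_bp": ev.width_bp,
                "category": ev.category,
                "annotations": sorted(ev.annotations),
                "truth_breakpoint_bp": trio.truth.breakpoint_bp,
                "breakpoint_contained": bool(lo <= trio.truth.breakpoint_bp <= hi),
            }
        )
    manifest["stages"]["localize"] = {
        "events_localized": len(events),
        "events_failed": failed,
        "breakpoint_containment": (
            sum(e["breakpoint_contained"] for e in events) / len(events) if events else None
        ),
        "events": events,
    }
    return events


def _stage_stats(trios, events, manifest):
    manifest["_current_stage"] = "stats"
    inv = {"parent-of-origin": [0, 0], "NAHR-negative": [0, 0]}
    for trio in trios:
        origin = trio.truth.parent_of_origin
        for parent_name in ("mother", "father"):
            parent = getattr(trio, parent_name)
            role = "parent-of-origin" if parent_name == origin else "NAHR-negative"
            for hap in parent["LCR22D"]:
                state = detect_inversion(hap)
                if state is None:
                    continue
                inv[role][0 if state else 1] += 1
    table = [inv["parent-of-origin"], inv["NAHR-negative"]]
    p_inv = fisher_2x2(table)
    n_inv = inv["parent-of-origin"][0] + inv["NAHR-negative"][0]
    n_tot = sum(sum(r) for r in table)
    origins = [t.truth.parent_of_origin for t in trios]
    try:
        ratio = origin_ratio(origins)
    except ValueError:
        ratio = None
    manifest["stages"]["stats"] = {
        "inversion_table": table,
        "inversion_fisher_p": p_inv,
        "inversion_prevalence_pct": proportion_summary(n_inv, n_tot)[0] if n_tot else None,
        "origin_female": origins.count("mother"),
        "origin_male": origins.count("father"),
        "origin_ratio_female_to_male": ratio,
    }


def _hash_manifest(manifest: dict) -> str:
    payload = {k: v for k, v in manifest.items() if k != "manifest_hash"}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_artifacts(config: RunConfig, manifest: dict) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    catalog = dense_catalog() if config.catalog == "dense" else default_catalog()
    map_io.write_cmap([h.labelmap for h in catalog.haplotypes.values()],
                      outdir / "catalog.cmap")
    with open(outdir / "report.txt", "w") as fh:
        fh.write(report(manifest))


def report(manifest: dict) -> str:
    """Human-readable run summary (pure function of the manifest)."""
    lines = []
    cfg = manifest.get("config", {})
    lines.append("lcrkit run report")
    lines.append(f"  seed={cfg.get('seed')} families={cfg.get('n_families')} "
                 f"coverage={cfg.get('coverage')}x catalog={cfg.get('catalog')}")
    stages = manifest.get("stages", {})
    if "simulate" in stages:
        oc = stages["simulate"]["origin_counts"]
        lines.append(f"  cohort: {stages['simulate']['n_families']} families "
                     f"({oc['mother']} maternal / {oc['father']} paternal origin)")
    if "assemble" in stages:
        a = stages["assemble"]
        m = a["molecules"]
        lines.append(
            f"  molecules: {m['total']} total, {m['assigned']} assigned, "
            f"{m['ambiguous']} ambiguous, {m['filtered']} filtered"
        )
        lines.append(
            f"  haplotypes: {a['haplotypes_complete']} complete, "
            f"{a['haplotypes_incomplete']} incomplete"
        )
        if "qc" in a:
            qc = a["qc"]
            fp = qc["fp_rate"]
            fn = qc["fn_rate"]
            lines.append(
                "  qc: fp={} fn={} density={:.1f}/100kbp".format(
                    "n/a" if fp is None else f"{fp:.3f}",
                    "n/a" if fn is None else f"{fn:.3f}",
                    qc["labels_per_100kbp"],
                )
            )
    for key, title in (
        ("groups_A_features", "LCR22A feature groups"),
        ("groups_A_labels", "LCR22A label groups"),
        ("groups_D_features", "LCR22D feature groups"),
    ):
        if key in stages:
            lines.append(f"  {title}: {len(stages[key])}")
            for grp, n in sorted(stages[key].items(), key=lambda kv: -kv[1]):
                lines.append(f"    {n:4d}  {grp}")
    if "localize" in stages:
        loc = stages["localize"]
        lines.append(
            f"  NAHR events: {loc['events_localized']} localized, {loc['events_failed']} failed"
        )
        if loc["events"]:
            lines.append("    family  origin  width_kbp  category  annotations")
            for e in loc["events"]:
                lines.append(
                    f"    {e['family_id']}  {e['parent_of_origin']}  "
                    f"{e['width_bp'] / 1000:.1f}  {e['category']}  "
                    f"{','.join(e['annotations']) or '-'}"
                )
        else:
            lines.append("    (none)")
    if "stats" in stages:
        s = stages["stats"]
        lines.append(
            f"  stats: inversion Fisher p={s['inversion_fisher_p']:.4f}; "
            f"inversion prevalence {s['inversion_prevalence_pct']}%; "
            f"origin ratio F:M={s['origin_ratio_female_to_male']}"
        )
    if manifest.get("failure_stage"):
        lines.append(f"  FAILED at stage {manifest['failure_stage']}: {manifest.get('error')}")
    lines.append(f"  manifest hash: {manifest.get('manifest_hash', '')[:16]}")
    return "\n".join(lines) + "\n"
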