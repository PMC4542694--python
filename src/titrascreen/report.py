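"""Pipeline orchestration and the final per-residue summary table.

:func:`run_pipeline` chains the stages — titration screen, structure
mapping, dose–response analysis, SAXS — from a single YAML/dict config in
which every stage is optional and independent.  The outcome is a
machine-readable JSON report plus a Markdown table in the style of a
mutagenesis summary: one row per residue with its screen group, structural
context and effect annotations (agonist ↑/↓/—, antagonist ↑/↓/—, pH
sensitivity ↓/—).

Effect-direction conventions (all configurable):

* pH sensitivity is marked ``down`` when the variant's acidic/neutral
  response ratio falls below ``sensitivity_ratio_cut`` (default 1.5) while
  the wild type is pH-dependent;
* residues whose primary effect is the loss of pH sensitivity get no
  agonist arrow — their altered neutral-pH potency is a facet of the same
  effect, not an affinity change;
* otherwise an EC50 fold-change vs wild type beyond ``ec50_fold_cut``
  (default 1.4) marks agonist potency ``up`` (EC50 decreased) or ``down``;
* the antagonist arrow compares each variant's suppression index with the
  wild type's at fold cut ``antagonism_fold_cut`` (default 1.3).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import doseresponse as dr
from . import peaklist_io as pio
from . import saxs as sx
from . import structure_map as sm
from . import synthetic_data as syn
from . import titration as ti

__all__ = ["run_pipeline", "records_to_frame", "effect_annotations"]

ARROW = {"up": "↑", "down": "↓", "none": "—", "n.d.": "n.d."}


def records_to_frame(records) -> pd.DataFrame:
    """Screen records as the canonical output table."""
    rows = []
    for r in records:
        rows.append(
            {
                "subunit": r.subunit,
                "residue": r.residue_number,
                "residue_type": r.residue_type,
                "dH_total": r.dH_total,
                "dN_total": r.dN_total,
                "csp_combined": r.csp_combined,
                "significant": r.significant,
                "f_low": r.f_low,
                "group": r.group,
                "pka": r.pka,
                "pka_stderr": r.pka_stderr,
                "missing_phs": ";".join(f"{p:g}" for p in sorted(r.missing_phs)),
            }
        )
    return pd.DataFrame(rows)


def effect_annotations(
    fits: Mapping[tuple[str, float], dr.DoseResponseFit],
    antagonism: Mapping[str, float],
    wt: str = "WT",
    ph_acidic: float = 6.3,
    ph_neutral: float = 7.4,
    ref_conc_um: Optional[float] = None,
    sensitivity_ratio_cut: float = 1.5,
    ec50_fold_cut: float = 1.4,
    antagonism_fold_cut: float = 1.3,
) -> dict[str, dict[str, str]]:
    """Per-variant effect directions derived from the dose-response fits."""
    variants = sorted({v for v, _ in fits})
    if (wt, ph_acidic) not in fits:
        raise ValueError(f"no acidic-pH fit for reference variant {wt!r}")
    wt_ec50 = fits[(wt, ph_acidic)].ec50
    wt_index = antagonism.get(wt)

    out: dict[str, dict[str, str]] = {}
    for v in variants:
        acid = fits.get((v, ph_acidic))
        neut = fits.get((v, ph_neutral))
        ann = {"ph_sensitivity": "none", "agonist": "none", "antagonist": "n.d."}
        ratio = None
        if acid and neut:
            ratio = dr.ph_dependency(acid, neut, ref_conc_um)
            acid.ph_dependency_ratio = ratio
            if v != wt and ratio < sensitivity_ratio_cut:
                ann["ph_sensitivity"] = "down"
        if acid and v != wt and ann["ph_sensitivity"] == "none":
            fold = wt_ec50 / acid.ec50
            if fold >= ec50_fold_cut:
                ann["agonist"] = "up"
            elif fold <= 1.0 / ec50_fold_cut:
                ann["agonist"] = "down"
        if v in antagonism and v != wt and wt_index:
            rel = antagonism[v] / wt_index
            if rel >= antagonism_fold_cut:
                ann["antagonist"] = "up"
            elif rel <= 1.0 / antagonism_fold_cut:
                ann["antagonist"] = "down"
            else:
                ann["antagonist"] = "none"
        out[v] = ann
    return out


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _stage_titration(cfg: dict, seed: int, log: list[str]):
    sconf_kwargs = cfg.get("config", {})
    sconf = ti.ScreenConfig(**sconf_kwargs)
    log.append(f"titration: config {sconf}")
    if cfg.get("synthetic") == "reference":
        scenario = syn.reference_screen_scenario(
            sigma_h=cfg.get("sigma_h", 0.0),
            sigma_n=cfg.get("sigma_n", 0.0),
            seed=seed,
        )
        peaklists, truth = syn.generate_titration(scenario, sconf)
        log.append(
            f"titration: synthetic reference-screen scenario, "
            f"{len(scenario.residues)} residues, seed {seed}"
        )
    else:
        paths = cfg.get("peaklists")
        if not paths:
            raise ValueError("titration stage: 'peaklists' or 'synthetic' required")
        if isinstance(paths, (str, Path)):
            paths = sorted(Path(paths).glob("*.csv"))
        peaklists = pio.read_series(paths, format=cfg.get("format", "csv"))
        truth = None
        log.append(f"titration: read {len(peaklists)} peak lists")
    series = ti.build_series(peaklists, sconf)
    records = []
    for s in series:
        rec = ti.compute_csp(s, sconf)
        rec = ti.classify_group(s, rec, sconf)
        if rec.significant:
            fit = ti.fit_pka(s, sconf)
            rec.pka, rec.pka_stderr = fit.pka, fit.pka_stderr
        records.append(rec)
    exchange = ti.detect_exchange_candidates(series)
    log.append(
        f"titration: {sum(r.significant for r in records)} significant, "
        f"{len(exchange)} exchange candidates"
    )
    return records, exchange, truth


def _stage_structure(cfg: dict, records, log: list[str]):
    if cfg.get("synthetic") == "reference":
        model, extra = syn.reference_screen_structure()
        labels = extra["functional_labels"]
        log.append("structure: synthetic reference-screen two-chain layout")
    else:
        path = cfg.get("path")
        if not path:
            raise ValueError("structure stage: 'path' or 'synthetic' required")
        model = sm.load_structure(
            path, cfg["chain_map"], cfg.get("residue_offset")
        )
        labels = {}
        for k, v in cfg.get("functional_labels", {}).items():
            sub, num = k.split(":")
            labels[(sub, int(num))] = v
        log.append(f"structure: loaded {len(model.residues)} residues from {path}")
    near_cut = cfg.get("near_his_cutoff", sm.NEAR_HIS_CUTOFF)
    iface_cut = cfg.get("interface_cutoff", sm.INTERFACE_CUTOFF)
    log.append(f"structure: near-His cutoff {near_cut} A, interface {iface_cut} A")
    prox = sm.his_proximity(model, cutoff=near_cut)
    iface = sm.interface_residues(model, cutoff=iface_cut)
    for p in prox:
        p.interface_flag = p.key in iface
    partition = (
        sm.interface_partition(records or [], prox, labels, model)
        if labels
        else None
    )
    return model, prox, iface, partition, labels


def _stage_dose(cfg: dict, seed: int, log: list[str]):
    ph_acid = cfg.get("ph_acidic", 6.3)
    ph_neut = cfg.get("ph_neutral", 7.4)
    if cfg.get("synthetic") == "reference":
        scenario = syn.reference_assay_scenario(
            n_cells=cfg.get("n_cells", 0), seed=seed
        )
        tables, truth = syn.generate_assay(scenario)
        mixtures = truth["mixture_tables"]
        alone = truth["agonist_alone"]
        log.append(
            f"dose: synthetic reference-screen assay, {len(scenario.variants)} variants"
        )
    else:
        path = cfg.get("table")
        if not path:
            raise ValueError("dose stage: 'table' or 'synthetic' required")
        all_tables = dr.read_response_tables(path)
        tables = {(t.variant, t.ph): t for t in all_tables}
        mixtures, alone = {}, None
        if cfg.get("antagonist_table"):
            ant = dr.read_response_tables(cfg["antagonist_table"])
            for t in ant:
                if t.variant == "agonist_alone":
                    alone = t
                else:
                    mixtures[t.variant] = t
        log.append(f"dose: read {len(tables)} variant/pH tables")
    fits: dict[tuple[str, float], dr.DoseResponseFit] = {}
    for key, table in sorted(tables.items()):
        try:
            fits[key] = dr.fit_hill(table)
        except dr.FitError as exc:
            log.append(f"dose: skipped {key}: {exc}")
    antagonism: dict[str, float] = {}
    if alone is not None:
        for v, mix in sorted(mixtures.items()):
            antagonism[v] = dr.antagonism_index(mix, alone)
    ref_conc = cfg.get("ref_conc_um")
    if ref_conc is None:
        concs = [set(t.concentration_um.tolist()) for t in tables.values()]
        shared = set.intersection(*concs) if concs else set()
        ref_conc = max(shared) if shared else None
    ann = effect_annotations(
        fits,
        antagonism,
        wt=cfg.get("wt_variant", "WT"),
        ph_acidic=ph_acid,
        ph_neutral=ph_neut,
        ref_conc_um=ref_conc,
        sensitivity_ratio_cut=cfg.get("sensitivity_ratio_cut", 1.5),
        ec50_fold_cut=cfg.get("ec50_fold_cut", 1.4),
        antagonism_fold_cut=cfg.get("antagonism_fold_cut", 1.3),
    )
    log.append(f"dose: reference concentration {ref_conc} uM")
    return fits, antagonism, ann


def _stage_saxs(cfg: dict, seed: int, log: list[str]):
    cutoff = cfg.get("beamstop_cutoff", sx.BEAMSTOP_Q_CUTOFF)
    profiles = []
    if cfg.get("synthetic"):
        spec = cfg["synthetic"]
        radii = spec.get("radii", [spec.get("radius", 30.0)])
        for i, radius in enumerate(radii):
            p, _ = syn.generate_saxs(
                radius, noise=spec.get("noise", 0.0), seed=seed + i
            )
            profiles.append((f"profile{i}_R{radius:g}", p.truncated(q_min=cutoff)))
        log.append(f"saxs: synthetic sphere profiles, radii {radii}")
    else:
        for path in cfg.get("profiles", []):
            profiles.append(
                (Path(path).stem, sx.read_saxs(path, beamstop_cutoff=cutoff))
            )
        log.append(f"saxs: read {len(profiles)} profiles")
    if not profiles:
        raise ValueError("saxs stage: 'profiles' or 'synthetic' required")
    results = {}
    for name, prof in profiles:
        fit = sx.guinier_fit(prof, qrg_limit=cfg.get("qrg_limit", 1.3))
        results[name] = {
            "rg": fit.rg,
            "i0": fit.i0,
            "q_range": list(fit.q_range),
            "qrg_max": fit.qrg_max,
            "r_squared": fit.r_squared,
        }
        log.append(f"saxs: {name} Rg = {fit.rg:.2f} A (qRg <= {fit.qrg_max:.2f})")
    comparison = None
    if len(profiles) == 2:
        comparison = sx.compare_profiles(profiles[0][1], profiles[1][1])
    return results, comparison


def run_pipeline(config, out_dir=None, seed: Optional[int] = None) -> dict:
    """Run the configured stages and assemble the summary report.

    ``config`` is a dict or YAML path with optional keys ``titration``,
    ``structure``, ``dose``, ``saxs`` plus global ``seed`` and
    ``variant_residue_map``.  Outputs (per-stage CSV/JSON plus
    ``report.json`` / ``report.md``) are written under ``out_dir`` when
    given.  Deterministic for fixed (config, seed).
    """
    cfg = _load_config(config)
    if not cfg or not any(
        k in cfg for k in ("titration", "structure", "dose", "saxs")
    ):
        raise ValueError(
            "empty pipeline config: provide at least one of "
            "titration/structure/dose/saxs"
        )
    seed = int(seed if seed is not None else cfg.get("seed", syn.DEFAULT_SEED))
    out_path = Path(out_dir) if out_dir else None
    if out_path:
        out_path.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed: {seed}"]

    records = exchange = truth = None
    prox = iface = partition = None
    fits = antagonism = annotations = None
    saxs_results = saxs_comparison = None

    if "titration" in cfg:
        records, exchange, truth = _stage_titration(cfg["titration"], seed, log)
        if out_path is not None:
            records_to_frame(records).to_csv(out_path / "screen.csv", index=False)
    if "structure" in cfg:
        _, prox, iface, partition, _ = _stage_structure(
            cfg["structure"], records, log
        )
        if out_path is not None:
            pd.DataFrame(
                [
                    {
                        "subunit": p.subunit,
                        "residue": p.residue_number,
                        "min_dist_to_his": p.min_dist_to_his,
                        "nearest_his": (
                            f"{p.nearest_his[0]}:{p.nearest_his[1]}"
                            if p.nearest_his
                            else ""
                        ),
                        "near_his": p.near_his,
                        "interface_flag": p.interface_flag,
                    }
                    for p in prox
                ]
            ).to_csv(out_path / "proximity.csv", index=False)
    if "dose" in cfg:
        fits, antagonism, annotations = _stage_dose(cfg["dose"], seed, log)
        if out_path is not None:
            dr.write_fits(list(fits.values()), out_path / "dose_fits.csv")
    if "saxs" in cfg:
        saxs_results, saxs_comparison = _stage_saxs(cfg["saxs"], seed, log)

    report = _assemble_report(
        cfg, records, exchange, prox, iface, partition,
        fits, antagonism, annotations, saxs_results, saxs_comparison, log,
    )
    if out_path is not None:
        with open(out_path / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
        with open(out_path / "report.md", "w") as fh:
            fh.write(render_markdown(report))
        with open(out_path / "pipeline.log", "w") as fh:
            fh.write("\n".join(log) + "\n")
    return report


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _assemble_report(
    cfg, records, exchange, prox, iface, partition,
    fits, antagonism, annotations, saxs_results, saxs_comparison, log,
) -> dict:
    variant_map = {
        v: tuple(k) for v, k in (cfg.get("variant_residue_map") or {}).items()
    }
    if not variant_map and annotations:
        variant_map = _default_variant_map(annotations)

    rows = []
    rec_by_key = {r.key: r for r in (records or [])}
    prox_by_key = {p.key: p for p in (prox or [])}
    effect_by_key = {}
    for v, ann in (annotations or {}).items():
        key = variant_map.get(v)
        if key:
            effect_by_key[tuple(key)] = {"variant": v, **ann}

    keys = sorted(set(rec_by_key) | set(effect_by_key))
    for key in keys:
        rec = rec_by_key.get(key)
        p = prox_by_key.get(key)
        eff = effect_by_key.get(key)
        rows.append(
            {
                "subunit": key[0],
                "residue": key[1],
                "group": rec.group if rec else None,
                "significant": rec.significant if rec else None,
                "pka": rec.pka if rec else None,
                "near_his": p.near_his if p else None,
                "interface_flag": p.interface_flag if p else None,
                "variant": eff["variant"] if eff else None,
                "ph_sensitivity": eff["ph_sensitivity"] if eff else None,
                "agonist": eff["agonist"] if eff else None,
                "antagonist": eff["antagonist"] if eff else None,
            }
        )

    report = {
        "rows": rows,
        "log": log,
        "exchange_candidates": [
            {"subunit": k[0], "residue": k[1], "missing_phs": sorted(m)}
            for k, m in (exchange or [])
        ],
        "interface_residues": (
            [f"{s}:{r}" for s, r in sorted(iface)] if iface else None
        ),
        "interface_partition": _stringify_keys(partition),
        "dose_fits": {
            f"{v}@{ph:g}": {
                "ec50_um": f.ec50,
                "hill": f.hill,
                "top": f.top,
                "ph_dependency_ratio": f.ph_dependency_ratio,
            }
            for (v, ph), f in (fits or {}).items()
        },
        "antagonism_index": antagonism,
        "saxs": saxs_results,
        "saxs_comparison": saxs_comparison,
    }
    return report


def _stringify_keys(obj):
    """Residue-key tuples -> 'SUBUNIT:NUM' strings, recursively (for JSON)."""
    if isinstance(obj, tuple) and len(obj) == 2 and isinstance(obj[0], str):
        return f"{obj[0]}:{obj[1]}"
    if isinstance(obj, dict):
        return {_stringify_keys(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, set)):
        return [_stringify_keys(v) for v in sorted(obj) if True] if isinstance(
            obj, set
        ) else [_stringify_keys(v) for v in obj]
    return obj


def _default_variant_map(annotations) -> dict:
    """Map variant names like 'R48A' onto residue keys via the name digits.

    Histidine-site variants of the emulated screen live on known subunits;
    anything else defaults to the basic subunit.  Supply
    ``variant_residue_map`` in the config to override.
    """
    nas_variants = {"Y21A", "H36A"}
    out = {}
    for v in annotations:
        digits = "".join(ch for ch in v if ch.isdigit())
        if not digits:
            continue
        sub = "NAS" if v in nas_variants else "NBS"
        out[v] = (sub, int(digits))
    return out


def render_markdown(report: dict) -> str:
    """Human-readable summary table; arrows encode effect directions."""
    lines = [
        "# Titration screen summary",
        "",
        "| residue | group | pKa | near His | interface | pH sensitivity "
        "| agonist | antagonist |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for row in report["rows"]:
        if not row["significant"] and row["variant"] is None:
            continue
        pka = f"{row['pka']:.2f}" if row["pka"] is not None else ""
        lines.append(
            "| {sub} {res} | {grp} | {pka} | {near} | {ifc} | {sens} | {ago} "
            "| {ant} |".format(
                sub=row["subunit"],
                res=row["residue"],
                grp=row["group"] or "",
                pka=pka,
                near={True: "yes", False: "no", None: ""}[row["near_his"]],
                ifc={True: "yes", False: "no", None: ""}[row["interface_flag"]],
                sens=ARROW.get(row["ph_sensitivity"], ""),
                ago=ARROW.get(row["agonist"], ""),
                ant=ARROW.get(row["antagonist"], ""),
            )
        )
    if report.get("exchange_candidates"):
        lines += [
            "",
            "Exchange-broadened residues (missing peaks): "
            + ", ".join(
                f"{e['subunit']} {e['residue']}"
                for e in report["exchange_candidates"]
            ),
        ]
    if report.get("saxs"):
        lines.append("")
        for name, r in report["saxs"].items():
            lines.append(f"SAXS {name}: Rg = {r['rg']:.2f} A")
    return "\n".join(lines) + "\n"
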