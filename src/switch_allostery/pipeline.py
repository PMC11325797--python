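"""Pipeline orchestration: run every requested analysis per system
(variant x nucleotide state) and compare systems against a reference.

A *system* bundles whatever inputs exist for one protein/nucleotide pair:
a trajectory (real files or a synthetic spec), melt curves, a kinetics trace,
and/or an STD peak table. Stages are independent: missing inputs produce an
explicit skip record, a failing stage is recorded and does not halt the rest,
and reruns of the same config are byte-identical (no timestamps in reports).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import contact_occupancy
from .dynamics import NonbondedParams, compute_rmsf, nonbonded_energy, normalize_energies
from .errors import ComparisonError, ConfigError, SwitchAllosteryError
from .fits import (
    MeltCurve,
    aggregate_tm,
    delta_tm,
    fit_boltzmann,
    fit_one_phase,
)
from .hbond import HBondCriteria, compare_networks, hbond_occupancy, persistence_tiers
from .stdnmr import analyze_peak_table, bin_interaction
from .structures import load_ligand_selection, load_regions, read_structure, read_trajectory
from .synth import (
    ContactPlant,
    CurveSpec,
    HBondPlant,
    SpectraSpec,
    TrajectorySpec,
    generate_curves,
    generate_trajectory,
)

_REGION_PAIRS = (("switch_I", "switch_II"), ("switch_II", "switch_III"),
                 ("switch_I", "switch_III"))


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(source) -> dict:
    if isinstance(source, Mapping):
        config = dict(source)
    else:
        with open(source) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "systems" not in config:
        raise ConfigError("pipeline config must be a mapping with a 'systems' key")
    if not isinstance(config["systems"], Mapping) or not config["systems"]:
        raise ConfigError("'systems' must be a non-empty mapping of label -> inputs")
    for label, entry in config["systems"].items():
        if not isinstance(entry, Mapping):
            raise ConfigError(f"system {label!r}: inputs must be a mapping")
    return config


def _build_trajectory(entry: Mapping, base_seed: int):
    if "synthetic" in entry:
        syn = dict(entry["synthetic"])
        syn_seed = int(base_seed) + int(syn.pop("seed_offset", 0))
        hplants = tuple(HBondPlant(**p) for p in syn.pop("hbond_plants", []))
        cplants = tuple(ContactPlant(**p) for p in syn.pop("contact_plants", []))
        spec = TrajectorySpec(
            hbond_plants=hplants, contact_plants=cplants, seed=syn_seed, **syn
        )
        return generate_trajectory(spec)
    topology = read_structure(entry["topology"])
    traj = read_trajectory(topology, entry["files"])
    return traj, None


def _melt_curves(entry: Mapping, base_seed: int):
    if "synthetic" in entry:
        syn = dict(entry["synthetic"])
        seed = int(base_seed) + int(syn.pop("seed_offset", 0))
        params = {k: syn.pop(k) for k in ("v50", "slope") if k in syn}
        spec = CurveSpec(model="boltzmann", params=params, seed=seed, **syn)
        curves, _ = generate_curves(spec)
        return [MeltCurve(x, y, replicate=i) for i, (x, y) in enumerate(curves)]
    df = pd.read_csv(entry["csv"])
    curves = []
    for rep, group in df.groupby("replicate"):
        group = group.sort_values("temperature")
        curves.append(
            MeltCurve(group["temperature"].to_numpy(),
                      group.iloc[:, 1].to_numpy(), replicate=rep)
        )
    return curves


def _run_stage(report: dict, name: str, func):
    try:
        report[name] = {"status": "ok", "result": func()}
    except SwitchAllosteryError as exc:
        report[name] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}


def run_pipeline(config) -> dict:
    """Execute all requested stages for every system; returns the run report.

    The report is a plain JSON-serializable dict: per system, H-bond
    occupancy matrices and tiers for the three switch-region pairs, RMSF
    profiles, optional normalized interaction energies, proton-contact
    profiles, STD-AF fingerprints, and Tm / kinetics fits, plus provenance
    (config hash, seed, package version).
    """
    config = load_config(config)
    seed = int(config.get("seed", 0))
    regions = load_regions(config.get("regions"))
    ligand = load_ligand_selection(config.get("ligand"))
    hb_conf = config.get("hbond", {})
    criteria = HBondCriteria(
        max_ha_distance=float(hb_conf.get("max_ha_distance", 2.4)),
        min_dha_angle=float(hb_conf.get("min_dha_angle", 120.0)),
    )
    tiers_conf = tuple(hb_conf.get("thresholds", (0.25, 0.5, 0.75)))
    radius = float(config.get("contacts", {}).get("radius", 6.0))

    report = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": seed,
            "package_version": __version__,
        },
        "systems": {},
    }
    raw_energies = []
    for label, entry in config["systems"].items():
        sysrep: dict = {}
        report["systems"][label] = sysrep

        traj = ledger = None
        if "trajectory" in entry:
            try:
                traj, ledger = _build_trajectory(entry["trajectory"], seed)
                if ledger is not None:
                    sysrep["synthetic_ledger"] = ledger
            except SwitchAllosteryError as exc:
                sysrep["trajectory"] = {
                    "status": "failed", "error": f"{type(exc).__name__}: {exc}"
                }

        if traj is not None:
            def hbond_stage():
                out = {}
                for a, b in _REGION_PAIRS:
                    mat = hbond_occupancy(traj, regions[a], regions[b], criteria)
                    out[f"{a}|{b}"] = {
                        "n_frames": mat.n_frames,
                        "atom_level": {
                            f"{k[0]}:{k[1]}->{k[2]}:{k[3]}": v
                            for k, v in sorted(mat.entries.items())
                        },
                        "residue_level": {
                            f"{k[0]}->{k[1]}": v
                            for k, v in sorted(mat.residue_entries.items())
                        },
                        "tiers": {
                            f"{k[0]}->{k[1]}": t
                            for k, t in sorted(
                                persistence_tiers(mat, tiers_conf, level="residue").items()
                            )
                        },
                    }
                return out

            def rmsf_stage():
                prof = compute_rmsf(traj)
                return {str(r): v for r, v in sorted(prof.per_residue.items())}

            def contacts_stage():
                prof = contact_occupancy(traj, ligand, radius)
                return {
                    "radius": radius,
                    "per_proton": {
                        lab: {
                            str(r): {
                                "proximity_occupancy": s.proximity_occupancy,
                                "closest_frequency": s.closest_frequency,
                            }
                            for r, s in sorted(entry2.items())
                        }
                        for lab, entry2 in prof.per_proton.items()
                    },
                    "union_occupancy": {
                        str(r): v for r, v in sorted(prof.union_occupancy.items())
                    },
                }

            _run_stage(sysrep, "hbonds", hbond_stage)
            _run_stage(sysrep, "rmsf", rmsf_stage)
            _run_stage(sysrep, "contacts", contacts_stage)

            if config.get("energy"):
                def energy_stage():
                    pconf = config["energy"].get("params", "bundled")
                    params = (
                        NonbondedParams.bundled_minimal()
                        if pconf == "bundled"
                        else NonbondedParams.from_csv(pconf)
                    )
                    vals = {}
                    for a, b in (("switch_I", "switch_II"), ("switch_II", "switch_III")):
                        e = nonbonded_energy(traj, regions[a], regions[b], params)
                        vals[f"{a}|{b}"] = e
                        raw_energies.append(
                            {"system": label, "region_pair": f"{a}|{b}", "energy": e}
                        )
                    return vals

                _run_stage(sysrep, "energy", energy_stage)
            else:
                sysrep["energy"] = {"status": "skipped",
                                    "reason": "no energy inputs configured"}
        else:
            for name in ("hbonds", "rmsf", "contacts", "energy"):
                sysrep.setdefault(
                    name, {"status": "skipped", "reason": "no trajectory inputs"}
                )

        if "melt" in entry:
            def melt_stage():
                curves = _melt_curves(entry["melt"], seed)
                fits = [fit_boltzmann(c, fix_normalization=True) for c in curves]
                agg = aggregate_tm(fits) if len(fits) >= 2 else None
                out = {
                    "replicates": [
                        {"v50": f.v50, "slope": f.slope, "v50_se": f.v50_se}
                        for f in fits
                    ]
                }
                if agg is not None:
                    out["tm_mean"] = agg.mean
                    out["tm_sd"] = agg.sd
                return out

            _run_stage(sysrep, "melt", melt_stage)
        else:
            sysrep["melt"] = {"status": "skipped", "reason": "no melt inputs"}

        if "kinetics" in entry:
            def kinetics_stage():
                kentry = entry["kinetics"]
                if "synthetic" in kentry:
                    syn = dict(kentry["synthetic"])
                    kseed = seed + int(syn.pop("seed_offset", 0))
                    params = {k: syn.pop(k) for k in ("y0", "plateau", "k") if k in syn}
                    spec = CurveSpec(model="one_phase", params=params,
                                     replicates=1, seed=kseed, **syn)
                    (x, y), = generate_curves(spec)[0]
                else:
                    df = pd.read_csv(kentry["csv"])
                    x, y = df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()
                fit = fit_one_phase(x, y)
                return {
                    "y0": fit.y0, "plateau": fit.plateau, "k": fit.k,
                    "k_se": fit.k_se,
                    "identifiability_warning": fit.identifiability_warning,
                }

            _run_stage(sysrep, "kinetics", kinetics_stage)
        else:
            sysrep["kinetics"] = {"status": "skipped", "reason": "no kinetics inputs"}

        if "stdaf" in entry:
            def stdaf_stage():
                sentry = entry["stdaf"]
                table = pd.read_csv(sentry["peak_table"]) if "peak_table" in sentry \
                    else pd.DataFrame(sentry["peaks"])
                results = analyze_peak_table(
                    table,
                    float(sentry["ligand_conc"]),
                    float(sentry["protein_conc"]),
                    str(sentry.get("reference_proton", "a")),
                )
                return {
                    lab: {
                        "astd": r.astd,
                        "sigma": r.sigma,
                        "normalized_pct": r.normalized_pct,
                        "normalized_sigma_pct": r.normalized_sigma_pct,
                        "bin": r.bin,
                    }
                    for lab, r in results.items()
                }

            _run_stage(sysrep, "stdaf", stdaf_stage)
        else:
            sysrep["stdaf"] = {"status": "skipped", "reason": "no STD inputs"}

    if raw_energies and config.get("reference") is not None:
        try:
            table = normalize_energies(
                pd.DataFrame(raw_energies), config["reference"]
            )
            report["normalized_energies"] = table.to_dict(orient="records")
        except SwitchAllosteryError as exc:
            report["normalized_energies_error"] = f"{type(exc).__name__}: {exc}"
    return report


def compare_systems(report: dict, reference: str,
                    hbond_threshold: float = 0.5) -> dict:
    """Per-system deltas against a reference system in the same report:
    delta-Tm, gained/lost residue-level H-bond pairs per region pair,
    energy ratios, and fingerprint bin shifts per proton."""
    systems = report.get("systems", {})
    if reference not in systems:
        raise ComparisonError(f"reference system {reference!r} not in report")
    ref = systems[reference]
    out = {"reference": reference, "systems": {}}
    for label, sysrep in systems.items():
        comp: dict = {}
        out["systems"][label] = comp

        if (
            ref.get("melt", {}).get("status") == "ok"
            and sysrep.get("melt", {}).get("status") == "ok"
            and "tm_mean" in ref["melt"]["result"]
            and "tm_mean" in sysrep["melt"]["result"]
        ):
            from .fits import AggregatedTm

            a = sysrep["melt"]["result"]
            b = ref["melt"]["result"]
            d = delta_tm(
                AggregatedTm(a["tm_mean"], a["tm_sd"], len(a["replicates"]),
                             tuple(r["v50"] for r in a["replicates"])),
                AggregatedTm(b["tm_mean"], b["tm_sd"], len(b["replicates"]),
                             tuple(r["v50"] for r in b["replicates"])),
            )
            comp["delta_tm"] = {"delta": d.delta, "sd": d.sd}

        if (
            ref.get("hbonds", {}).get("status") == "ok"
            and sysrep.get("hbonds", {}).get("status") == "ok"
        ):
            hcomp = {}
            for pair_key, ref_mat in ref["hbonds"]["result"].items():
                sys_mat = sysrep["hbonds"]["result"].get(pair_key)
                if sys_mat is None:
                    continue
                ref_present = {
                    k for k, v in ref_mat["residue_level"].items()
                    if v >= hbond_threshold
                }
                sys_present = {
                    k for k, v in sys_mat["residue_level"].items()
                    if v >= hbond_threshold
                }
                hcomp[pair_key] = {
                    "gained": sorted(sys_present - ref_present),
                    "lost": sorted(ref_present - sys_present),
                    "shared": sorted(ref_present & sys_present),
                }
            comp["hbonds"] = hcomp

        if (
            ref.get("energy", {}).get("status") == "ok"
            and sysrep.get("energy", {}).get("status") == "ok"
        ):
            comp["energy_ratio"] = {
                pair: sysrep["energy"]["result"][pair] / ref_val
                for pair, ref_val in ref["energy"]["result"].items()
                if abs(ref_val) > 1e-12 and pair in sysrep["energy"]["result"]
            }

        if (
            ref.get("stdaf", {}).get("status") == "ok"
            and sysrep.get("stdaf", {}).get("status") == "ok"
        ):
            shifts = {}
            for proton, ref_entry in ref["stdaf"]["result"].items():
                sys_entry = sysrep["stdaf"]["result"].get(proton)
                if sys_entry is None:
                    continue
                shifts[proton] = {
                    "reference_bin": ref_entry["bin"],
                    "system_bin": sys_entry["bin"],
                    "shifted": ref_entry["bin"] != sys_entry["bin"],
                    "reference_pct": ref_entry["normalized_pct"],
                    "system_pct": sys_entry["normalized_pct"],
                }
            comp["fingerprint"] = shifts
    return out


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
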