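"""End-to-end orchestration: inputs -> profiles -> counting + Bayesian
analysis -> transport summaries -> comparison report.

A single structured config (YAML-friendly dict) drives everything; every
stage output is a pure function of (inputs, config, seed) and lands in
the output directory with provenance headers. Two-system configs yield
the headline between-system comparisons: permeability ratios by both
methods and the partition-coefficient ratio at each system's own h.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bayes as _bayes
from . import crossings as _crossings
from . import profiles as _profiles
from . import synth as _synth
from . import transport as _transport
from .io import (MembraneGeometry, load_permeant_trajectories,
                 write_permeant_trajectories, write_profile_table)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("memperm")

_SYSTEM_KEYS = {"input", "profile", "n_permeants", "t_total", "dt_step",
                "save_every", "Lx", "Ly", "H", "temperature", "permeant_type"}
_TOP_KEYS = {"output_dir", "seed", "geometry", "n_bins", "lags_ps",
             "bayes", "systems"}
_BAYES_KEYS = {"enabled", "n_bins", "n_f", "n_logd", "n_modes", "r_max",
               "n_radial", "mode", "n_burn", "n_sweeps"}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``systems`` maps a system label to either ``{"input": path}`` (a
    permeant-trajectory TSV) or a synthetic run description with a
    ``profile`` key (``oxygen-like`` / ``water-like`` or explicit cosine
    coefficients) plus optional run-spec overrides. Exactly one input
    mode per system.
    """

    systems: dict
    geometry: MembraneGeometry
    output_dir: Path = Path("memperm_out")
    seed: int = 0
    n_bins: int = 100
    lags_ps: tuple[float, ...] = _bayes.DEFAULT_LAGS_PS
    bayes: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "systems" not in raw or not raw["systems"]:
            raise ValueError("config must define at least one system")
        for name, sysc in raw["systems"].items():
            bad = set(sysc) - _SYSTEM_KEYS
            if bad:
                raise ValueError(f"system {name!r}: unknown keys {sorted(bad)}")
            if ("input" in sysc) == ("profile" in sysc):
                raise ValueError(f"system {name!r}: exactly one of "
                                 "'input' or 'profile' is required")
        geo = raw.get("geometry", {})
        bayes_cfg = dict(raw.get("bayes", {}))
        bad = set(bayes_cfg) - _BAYES_KEYS
        if bad:
            raise ValueError(f"bayes: unknown keys {sorted(bad)}")
        return cls(
            systems=dict(raw["systems"]),
            geometry=MembraneGeometry(
                half_thickness=float(geo.get("half_thickness", 15.0)),
                z_mid=float(geo.get("z_mid", 4.0)),
                water_zone=tuple(geo["water_zone"]) if "water_zone" in geo
                else None),
            output_dir=Path(raw.get("output_dir", "memperm_out")),
            seed=int(raw.get("seed", 0)),
            n_bins=int(raw.get("n_bins", 100)),
            lags_ps=tuple(raw.get("lags_ps", _bayes.DEFAULT_LAGS_PS)),
            bayes=bayes_cfg,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps({"systems": self.systems, "seed": self.seed,
                           "n_bins": self.n_bins, "lags": self.lags_ps,
                           "bayes": self.bayes,
                           "geometry": [self.geometry.half_thickness,
                                        self.geometry.z_mid]},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _get_trajectories(name: str, sysc: dict, seed: int):
    if "input" in sysc:
        return load_permeant_trajectories(sysc["input"])
    prof_key = sysc["profile"]
    H = float(sysc.get("H", 70.0))
    if prof_key == "oxygen-like":
        prof = _synth.oxygen_like_spec(H)
    elif prof_key == "water-like":
        prof = _synth.water_like_spec(H)
    elif isinstance(prof_key, dict):
        prof = _synth.ProfileSpec(
            H=H, f_coeffs=prof_key["f_coeffs"],
            log_dperp_coeffs=prof_key["log_dperp_coeffs"],
            log_dpar_coeffs=prof_key["log_dpar_coeffs"])
    else:
        raise ValueError(f"system {name!r}: unknown profile {prof_key!r}")
    run = _synth.SyntheticRunSpec(
        profile=prof,
        n_permeants=int(sysc.get("n_permeants", 50)),
        t_total=float(sysc.get("t_total", 20000.0)),
        dt_step=float(sysc.get("dt_step", 0.05)),
        save_every=float(sysc.get("save_every", 1.0)),
        seed=seed,
        Lx=float(sysc.get("Lx", 40.0)), Ly=float(sysc.get("Ly", 40.0)),
        temperature=float(sysc.get("temperature", 298.0)),
        permeant_type=str(sysc.get("permeant_type", "oxygen-like")))
    return _synth.simulate_permeants(run)


def _analyze_system(name, sysc, cfg: RunConfig, seed: int, outdir: Path):
    log.info("system %s: acquiring trajectories", name)
    trajs = _get_trajectories(name, sysc, seed)
    write_permeant_trajectories(trajs, outdir / f"{name}_trajectories.tsv")
    geo = cfg.geometry
    Lx, Ly, H = trajs[0].box
    area = Lx * Ly
    t_sim = float(trajs[0].times[-1] - trajs[0].times[0])

    pmf = _profiles.estimate_pmf(trajs, cfg.n_bins, geo)
    write_profile_table(pmf, outdir / f"{name}_pmf.tsv")
    conc = _profiles.water_concentration(len(trajs), pmf, area,
                                         trajs=trajs, geometry=geo)
    c_w = conc["boltzmann-integral"].per_A3

    logs = [_crossings.detect_events(t, geo) for t in trajs]
    counting = _crossings.counting_permeability(logs, t_sim, area, c_w)
    times = _crossings.characteristic_times(logs)
    try:
        l_par, l_par_se = _crossings.lateral_escape_distance(logs)
    except ValueError:
        l_par, l_par_se = None, None
    h = 2 * geo.half_thickness
    try:
        K = _profiles.partition_coefficient(pmf, h).K
    except ValueError:
        # interior bins never visited (high barrier, short run)
        log.warning("system %s: membrane interior unsampled; K unavailable",
                    name)
        K = None

    result = {
        "n_permeants": len(trajs), "t_sim_ps": t_sim, "area_A2": area,
        "c_w_per_A3": c_w, "c_w_molar": conc["boltzmann-integral"].molar,
        "P_counting_cms": counting.p_cms,
        "P_counting_ci_cms": list(counting.ci_cms),
        "effective_crossings": counting.effective_count,
        "K": K, "h_A": h,
        "tau_entr_ps": times.tau_entr, "tau_esc_ps": times.tau_esc,
        "L_par_A": l_par, "L_par_se_A": l_par_se,
    }

    bcfg = cfg.bayes
    if bcfg.get("enabled", False):
        log.info("system %s: Bayesian analysis", name)
        n_bins_ba = int(bcfg.get("n_bins", 25))
        mode = str(bcfg.get("mode", "z"))
        counts = _bayes.count_transitions(
            trajs, n_bins_ba, cfg.lags_ps,
            r_max=float(bcfg.get("r_max", 50.0)),
            n_radial=int(bcfg.get("n_radial", 20)),
            radial=(mode == "radial"))
        model = _bayes.BayesModel(
            H=H, temperature=trajs[0].temperature, n_bins=n_bins_ba,
            n_f=int(bcfg.get("n_f", 10)), n_logd=int(bcfg.get("n_logd", 6)),
            n_modes=int(bcfg.get("n_modes", 10)),
            r_max=float(bcfg.get("r_max", 50.0)), seed=seed)
        summary = _bayes.sample_posterior(
            counts, model, mode=mode,
            n_burn=int(bcfg.get("n_burn", 200)),
            n_sweeps=int(bcfg.get("n_sweeps", 200)))
        diffusion = _bayes.extrapolate_infinite_lag(summary)
        write_profile_table(diffusion, outdir / f"{name}_diffusion.tsv")
        ba_pmf = summary.free_energy(trajs[0].temperature)
        lo_w, hi_w = geo.water_zone_for_box(H)
        ref_mask = (np.abs(ba_pmf.z) >= lo_w) & (np.abs(ba_pmf.z) <= hi_w)
        ba_pmf.f_ref = float(ba_pmf.values[ref_mask].mean())
        write_profile_table(ba_pmf, outdir / f"{name}_pmf_bayes.tsv")
        result["P_isd_cms"] = _transport.permeability_isd(ba_pmf, diffusion, h)
        result["P_par_cms"] = _transport.radial_permeability(ba_pmf, diffusion, h)
        result["bayes_acceptance"] = {str(k): v
                                      for k, v in summary.acceptance.items()}
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write the comparison report.

    Returns the report dict; artifacts (trajectory/profile TSVs, report
    JSON, human-readable summary) land in ``config.output_dir``. Stage
    errors abort with the system and stage named; prior outputs persist.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"config_hash": config.config_hash(), "seed": config.seed,
              "systems": {}, "ratios": {}}
    for i, (name, sysc) in enumerate(config.systems.items()):
        seed = (config.seed + 104729 * i) % 2 ** 31
        try:
            report["systems"][name] = _analyze_system(
                name, sysc, config, seed, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage failed for system {name!r}: {exc}") from exc

    names = list(report["systems"])
    if len(names) >= 2:
        a, b = names[0], names[1]
        sa, sb = report["systems"][a], report["systems"][b]
        report["ratios"] = {
            "P_counting": sa["P_counting_cms"] / sb["P_counting_cms"]
            if sb["P_counting_cms"] else None,
            "K": (sa["K"] / sb["K"]
                  if sa["K"] is not None and sb["K"] else None),
            "pair": [a, b],
        }
        if "P_isd_cms" in sa and "P_isd_cms" in sb:
            report["ratios"]["P_isd"] = sa["P_isd_cms"] / sb["P_isd_cms"]

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(f"memperm report (config {report['config_hash']}, "
                 f"seed {config.seed})\n")
        for name, s in report["systems"].items():
            fh.write(f"\n[{name}]\n")
            fh.write(f"  P (counting) = {s['P_counting_cms']:.4g} cm/s "
                     f"95% CI {s['P_counting_ci_cms'][0]:.4g}-"
                     f"{s['P_counting_ci_cms'][1]:.4g}\n")
            if "P_isd_cms" in s:
                fh.write(f"  P (ISD)      = {s['P_isd_cms']:.4g} cm/s\n")
            if s["K"] is not None:
                fh.write(f"  K(h={s['h_A']:.1f} A) = {s['K']:.4g}\n")
        if report["ratios"]:
            r = report["ratios"]
            def fmt(v):
                return f"{v:.3g}" if v is not None else "n/a"
            fh.write(f"\nratios {r['pair'][0]}/{r['pair'][1]}: "
                     f"P_counting={fmt(r['P_counting'])} K={fmt(r['K'])}\n")
    return report
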