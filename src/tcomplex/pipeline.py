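"""End-to-end orchestration: prepare -> interface -> r_cut -> sample ->
locate the transient complex -> activation angles -> report.

A run is fully described by a :class:`RunConfig` (serializable to YAML) and
one root seed; every artifact lands in the output directory and the JSON
report records where.  Stage failures raise :class:`StageError` with the
stage name; artifacts produced before the failure are retained.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from ._version import __version__
from .contacts import find_interface, select_interaction_loci
from .errors import ConfigurationError, StageError
from .geometry import angle_histograms, build_frame, compute_angles, compute_ensemble_angles
from .sampling import (
    BindingGeometry,
    SamplingSpec,
    determine_rcut,
    run_sampling,
)
from .structure import load_complex, validate_native, write_complex
from .synthetic import ToyComplexSpec, make_toy_complex
from .transition import build_profile, extract_ensemble, fit_two_state

log = logging.getLogger("tcomplex")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    outdir: str
    structure_file: str | None = None
    assignment: dict | str | None = None
    toy: dict | None = None                 # ToyComplexSpec fields
    sampling: dict = field(default_factory=dict)    # SamplingSpec overrides
    seed: int = 0
    interface_cutoff: float = 5.0
    tail_cutoff: float = 8.0
    elimination_radius: float = 3.5
    profile_min_count: int = 50
    sigma_mode: str = "rms"
    sloped_baselines: bool = False
    bin_width: float = 5.0
    axis_method: str = "gyration"

    def __post_init__(self):
        if (self.structure_file is None) == (self.toy is None):
            raise ConfigurationError(
                "exactly one of structure_file (+assignment) or toy must be given"
            )
        if self.structure_file is not None and self.assignment is None:
            raise ConfigurationError("structure_file requires an assignment spec")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError(f"run config {path} is not a mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(f"bad run config {path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def sampling_spec(self) -> SamplingSpec:
        kwargs = dict(self.sampling)
        kwargs.setdefault("seed", self.seed)
        if self.toy is not None:
            kwargs.setdefault("target_clashfree", 100_000)
            kwargs.setdefault("rcut_pilot", 100_000)
            # the auto r_cut floor targets tight protein interfaces; the toy's
            # deliberately wide native well needs the shell fixed explicitly
            kwargs.setdefault("r_cut", 8.0)
        return SamplingSpec(**kwargs)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
            log.info("stage %-10s done in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run report (also written to JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")
    spec = config.sampling_spec()
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tcomplex_version": __version__,
        "python": platform.python_version(),
        "seed": spec.seed,
        "timings_s": {},
        "artifacts": {},
    }
    t_start = time.perf_counter()

    def timed(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:
            _write_report(outdir, report)
            raise StageError(name, exc) from exc
        report["timings_s"][name] = round(time.perf_counter() - t0, 3)
        return out

    # -- prepare -------------------------------------------------------------
    def prepare():
        if config.toy is not None:
            model, truth = make_toy_complex(ToyComplexSpec(**config.toy))
            report["input"] = {"kind": "toy", **config.toy}
            report["toy_ground_truth"] = {
                "native_gamma": truth.native_gamma,
                "native_phi": truth.native_phi,
                "native_pair_count": len(truth.native_pairs),
            }
        else:
            model = load_complex(config.structure_file, config.assignment)
            report["input"] = {"kind": "pdb", "structure_file": str(config.structure_file)}
        validation = validate_native(model, clash_distance=spec.clash_distance,
                                     interface_cutoff=config.interface_cutoff)
        report["native_validation"] = {
            "min_cross_distance": validation.min_cross_distance,
            "interface_pairs_le_cutoff": validation.interface_pairs,
        }
        write_complex(model, outdir / "normalized.pdb",
                      remark="normalized heavy-atom complex (tcomplex)")
        report["artifacts"]["normalized_structure"] = "normalized.pdb"
        return model

    model = timed("prepare", prepare)

    # -- interface + loci ----------------------------------------------------
    def interface():
        pairs = find_interface(model, cutoff=config.interface_cutoff,
                               tail_cutoff=config.tail_cutoff)
        loci = select_interaction_loci(pairs, config.elimination_radius, model=model)
        loci.to_table(model).to_csv(outdir / "loci.tsv", sep="\t", index=False)
        report["artifacts"]["loci_table"] = "loci.tsv"
        report["interface"] = {
            "pair_count": len(pairs),
            "retained_native_pairs": loci.native_count,
            "nc_native": loci.count_contacts(model.mobile.coords, model.fixed.coords),
        }
        return pairs, loci

    pairs, loci = timed("interface", interface)
    geometry = BindingGeometry.from_model(model, pairs)

    # -- r_cut ---------------------------------------------------------------
    def rcut():
        if spec.r_cut is None:
            spec.r_cut = determine_rcut(model, spec, geometry=geometry)
        report["r_cut"] = spec.r_cut
        return spec.r_cut

    timed("r_cut", rcut)

    # -- sampling ------------------------------------------------------------
    def sample():
        store = run_sampling(model, loci, spec, geometry=geometry)
        store.save(outdir / "ensemble.tsv")
        report["artifacts"]["ensemble_store"] = "ensemble.tsv"
        report["sampling"] = {
            "clash_free_configurations": len(store),
            "clash_distance": spec.clash_distance,
        }
        return store

    store = timed("sample", sample)

    # -- transition / transient ensemble ------------------------------------
    def locate():
        profile = build_profile(store, min_count=config.profile_min_count,
                                sigma_mode=config.sigma_mode)
        profile = fit_two_state(profile, sloped_baselines=config.sloped_baselines)
        profile.save(outdir / "transition_profile.tsv", outdir / "transition_fit.json")
        report["artifacts"]["transition_profile"] = "transition_profile.tsv"
        report["artifacts"]["transition_fit"] = "transition_fit.json"
        ensemble = extract_ensemble(store, profile.nc_star_rounded)
        ensemble.members.save(outdir / "transient_ensemble.tsv")
        report["artifacts"]["transient_ensemble"] = "transient_ensemble.tsv"
        report["transition"] = {
            **profile.fit_summary(),
            "ensemble_size": ensemble.member_count,
        }
        return profile, ensemble

    profile, ensemble = timed("locate", locate)

    # -- activation angles ---------------------------------------------------
    def angles():
        frame = build_frame(model, axis_method=config.axis_method)
        native = compute_angles(frame, model, axis_method=config.axis_method)
        table = compute_ensemble_angles(ensemble.members, model, geometry,
                                        frame=frame, axis_method=config.axis_method)
        table.to_csv(outdir / "transient_angles.tsv", sep="\t", index=False)
        hists = angle_histograms(ensemble, model, geometry, frame=frame,
                                 bin_width=config.bin_width,
                                 axis_method=config.axis_method, angles=table)
        hists.gamma_hist.to_csv(outdir / "gamma_hist.tsv", sep="\t", index=False)
        hists.phi_hist.to_csv(outdir / "phi_hist.tsv", sep="\t", index=False)
        report["artifacts"]["angle_table"] = "transient_angles.tsv"
        report["artifacts"]["gamma_histogram"] = "gamma_hist.tsv"
        report["artifacts"]["phi_histogram"] = "phi_hist.tsv"
        report["angles"] = {
            "native_gamma": native.gamma,
            "native_phi": native.phi,
            **{k: v for k, v in hists.summary().items()
               if k not in ("native_gamma", "native_phi")},
        }

    timed("angles", angles)

    report["timings_s"]["total"] = round(time.perf_counter() - t_start, 3)
    _write_report(outdir, report)
    return report


def _write_report(outdir: Path, report: dict) -> None:
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
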