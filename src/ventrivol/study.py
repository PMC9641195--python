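"""End-to-end study harness: three volume measurements per subject on a
phantom cohort (or a directory of mesh/mask pairs), a per-method summary
table, and agreement reports for the method pairs of interest.

Mirrors the clinical three-method design: the slice (Simpson) engine plays
the dedicated-platform role ("pdp"), the polygon engine on the smooth
surface is the platform-similar mesh measurement ("vrps"), and the polygon
engine on the inner-blood-pool surface is the blood-pool-only measurement
("vribp").  Agreement is reported per stratum (LV-like bullets, RV-like
crescents) for pdp-vs-vrps and vrps-vs-vribp.

Everything written to the output bundle (CSV/JSON) is byte-reproducible
given the seed; the run log additionally records wall-clock timings, which
are not.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .agreement import AgreementResults, MethodComparison
from .engines import mesh_volume, slice_stack_volume, VoxelMask
from .mesh import read_stl
from .phantoms import COHORT_COLUMNS, lv_population, make_cohort, rv_population

__all__ = ["StudyConfig", "StudyResults", "VolumeStudy", "run_study"]

logger = logging.getLogger(__name__)

_METHOD_COLS = {"pdp": "pdp_cm3", "vrps": "vrps_cm3", "vribp": "vribp_cm3"}
_DEFAULT_PAIRS = (("pdp", "vrps"), ("vrps", "vribp"))


@dataclass
class StudyConfig:
    """Configuration of one study run.

    Exactly one input source: either a generated cohort (the default; all
    cohort parameters below apply) or ``input_dir``, a directory of
    per-subject files named ``<stem>_smooth.stl``, ``<stem>_ibp.stl`` and
    ``<stem>_mask.nii[.gz]``.
    """

    n: int = 20
    seed: int = 7
    strata: tuple = ("lv", "rv")
    method_noise_cm3: float = 4.0
    method_bias_cm3: float = 0.0
    amplitude_mean_mm: float = 2.0
    amplitude_sd_mm: float = 0.5
    mesh_resolution: int = 5000
    voxel_spacing_mm: float = 0.8
    pairs: tuple = _DEFAULT_PAIRS
    input_dir: Optional[str] = None
    out_dir: str = "study_out"

    def __post_init__(self):
        if self.input_dir is not None and self.n != StudyConfig.n:
            raise ValueError("configure either a generated cohort or input_dir, not both")
        for a, b in self.pairs:
            if a not in _METHOD_COLS or b not in _METHOD_COLS:
                raise ValueError(f"unknown method in pair ({a}, {b})")
        unknown = set(self.strata) - {"lv", "rv"}
        if unknown:
            raise ValueError(f"unknown strata {sorted(unknown)}; expected subset of ('lv','rv')")

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        """Load from a single YAML or JSON document."""
        with open(path) as fh:
            text = fh.read()
        if os.fspath(path).endswith((".yaml", ".yml")):
            import yaml

            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
        doc = {k: tuple(v) if isinstance(v, list) else v for k, v in (doc or {}).items()}
        if "pairs" in doc:
            doc["pairs"] = tuple(tuple(p) for p in doc["pairs"])
        return cls(**doc)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["strata"] = list(self.strata)
        d["pairs"] = [list(p) for p in self.pairs]
        return d


@dataclass
class StudyResults:
    """Everything a study run produced, plus where it was written."""

    config: StudyConfig
    per_subject: pd.DataFrame
    summary: pd.DataFrame
    reports: dict  # {(stratum, a, b) keyed as "stratum_a_vs_b": AgreementResults}
    n_failed: int
    out_dir: Optional[str]

    @property
    def exit_status(self) -> int:
        return 0 if self.n_failed == 0 else 2

    def summary_text(self) -> str:
        """Mean +/- SD and range per method and stratum, clinical-table style."""
        lines = ["Volumetric analysis by method (cm^3)", "=" * 60]
        for stratum, grp in self.per_subject.groupby("stratum", sort=False):
            lines.append(f"[{stratum}]  n = {len(grp)}")
            for method, col in _METHOD_COLS.items():
                v = grp[col].dropna()
                if not len(v):
                    continue
                lines.append(
                    f"  {method:6s} {v.mean():7.1f} +/- {v.std(ddof=1):5.1f}"
                    f"   range {v.min():.1f}-{v.max():.1f}"
                )
        return "\n".join(lines)


class VolumeStudy:
    """Model-style wrapper: ``VolumeStudy(config).fit()`` runs the study."""

    def __init__(self, config: Optional[StudyConfig] = None, **kwargs):
        self.config = config or StudyConfig(**kwargs)

    def fit(self, write: bool = True) -> StudyResults:
        return run_study(self.config, write=write)


# ---------------------------------------------------------------------------


def _generate_cohort(cfg: StudyConfig) -> tuple[pd.DataFrame, int]:
    ss = np.random.SeedSequence(cfg.seed)
    stratum_seeds = {s: int(c.generate_state(1)[0] % (2**31 - 1)) for s, c in
                     zip(("lv", "rv"), ss.spawn(2))}
    frames = []
    for stratum in cfg.strata:
        pop = (lv_population if stratum == "lv" else rv_population)(
            amplitude_mean=cfg.amplitude_mean_mm, amplitude_sd=cfg.amplitude_sd_mm
        )
        t0 = time.perf_counter()
        df = make_cohort(
            n=cfg.n,
            seed=stratum_seeds[stratum],
            population=pop,
            method_noise=cfg.method_noise_cm3,
            method_bias=cfg.method_bias_cm3,
            mesh_resolution=cfg.mesh_resolution,
            voxel_spacing=cfg.voxel_spacing_mm,
        )
        logger.info("stratum %s: %d subjects in %.1f s", stratum, len(df), time.perf_counter() - t0)
        df.insert(1, "stratum", stratum)
        df["subject_id"] = [f"{stratum.upper()}{i + 1:03d}" for i in range(len(df))]
        frames.append(df)
    return pd.concat(frames, ignore_index=True), 0


def _load_directory(cfg: StudyConfig) -> tuple[pd.DataFrame, int]:
    """Measure a directory of exported subject files; per-subject failures
    are recorded (NaN row) and the study continues."""
    stems = sorted(
        f[: -len("_smooth.stl")]
        for f in os.listdir(cfg.input_dir)
        if f.endswith("_smooth.stl")
    )
    if not stems:
        raise FileNotFoundError(f"no '*_smooth.stl' subjects found in {cfg.input_dir}")
    rows, n_failed = [], 0
    for stem in stems:
        row = {"subject_id": stem, "stratum": "all", "shape": "file", "truth_cm3": np.nan,
               "pdp_cm3": np.nan, "vrps_cm3": np.nan, "vribp_cm3": np.nan}
        try:
            base = os.path.join(cfg.input_dir, stem)
            mask_path = next(
                p for p in (base + "_mask.nii.gz", base + "_mask.nii") if os.path.exists(p)
            )
            row["vrps_cm3"] = mesh_volume(read_stl(base + "_smooth.stl")).volume_cm3
            row["pdp_cm3"] = slice_stack_volume(VoxelMask.from_nifti(mask_path)).volume_cm3
            if os.path.exists(base + "_ibp.stl"):
                row["vribp_cm3"] = mesh_volume(read_stl(base + "_ibp.stl")).volume_cm3
            sidecar = base + ".json"
            if os.path.exists(sidecar):
                with open(sidecar) as fh:
                    row["truth_cm3"] = json.load(fh).get("truth_volume_cm3", np.nan)
        except (Exception,) as exc:  # noqa: BLE001 - per-subject isolation
            n_failed += 1
            logger.error("subject %s failed: %s", stem, exc)
        rows.append(row)
    cols = ["subject_id", "stratum"] + COHORT_COLUMNS[1:]
    return pd.DataFrame(rows, columns=cols), n_failed


def _summarise(per_subject: pd.DataFrame) -> pd.DataFrame:
    recs = []
    for stratum, grp in per_subject.groupby("stratum", sort=False):
        for method, col in _METHOD_COLS.items():
            v = grp[col].dropna()
            if not len(v):
                continue
            recs.append(
                {
                    "stratum": stratum,
                    "method": method,
                    "n": int(len(v)),
                    "mean_cm3": v.mean(),
                    "sd_cm3": v.std(ddof=1),
                    "min_cm3": v.min(),
                    "max_cm3": v.max(),
                }
            )
    return pd.DataFrame(recs)


def run_study(cfg: StudyConfig, write: bool = True) -> StudyResults:
    """Run the full three-method study described by *cfg*.

    Produces the per-subject volume table, the per-method summary, and one
    agreement report per (stratum, method pair); optionally writes the
    bundle (CSVs, JSONs, config echo, log) under ``cfg.out_dir``.
    """
    t_start = time.perf_counter()
    if cfg.input_dir is not None:
        per_subject, n_failed = _load_directory(cfg)
    else:
        per_subject, n_failed = _generate_cohort(cfg)

    summary = _summarise(per_subject)

    reports: dict[str, AgreementResults] = {}
    for stratum, grp in per_subject.groupby("stratum", sort=False):
        for a, b in cfg.pairs:
            sub = grp[[_METHOD_COLS[a], _METHOD_COLS[b]]].dropna()
            if len(sub) < 3:
                logger.warning("skipping %s %s-vs-%s: fewer than 3 complete pairs", stratum, a, b)
                continue
            res = MethodComparison(
                sub[_METHOD_COLS[a]].to_numpy(),
                sub[_METHOD_COLS[b]].to_numpy(),
                labels=(a, b),
            ).fit()
            reports[f"{stratum}_{a}_vs_{b}"] = res

    out_dir = None
    if write:
        out_dir = cfg.out_dir
        os.makedirs(out_dir, exist_ok=True)
        per_subject.to_csv(os.path.join(out_dir, "per_subject.csv"), index=False)
        summary.to_csv(os.path.join(out_dir, "summary.csv"), index=False)
        for key, res in reports.items():
            res.to_json(os.path.join(out_dir, f"agreement_{key}.json"))
        with open(os.path.join(out_dir, "config.json"), "w") as fh:
            json.dump(cfg.as_dict(), fh, indent=2)
        with open(os.path.join(out_dir, "run_log.txt"), "w") as fh:
            fh.write(f"ventrivol {__version__}\nseed {cfg.seed}\n")
            fh.write(f"subjects {len(per_subject)}  failed {n_failed}\n")
            fh.write(f"elapsed_s {time.perf_counter() - t_start:.2f}\n")

    result = StudyResults(cfg, per_subject, summary, reports, n_failed, out_dir)
    logger.info("study complete: %d subjects, %d failed, %.1f s",
                len(per_subject), n_failed, time.perf_counter() - t_start)
    return result
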