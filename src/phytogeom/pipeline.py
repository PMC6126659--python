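"""End-to-end orchestration: structure comparison and spectra jobs.

Consumes a YAML run configuration, produces TSV reports plus a plain-text
log. Rows fail independently: a structure that cannot be measured leaves a
flagged row and the run continues; the returned exit code counts failures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dimer_geometry import geometry_table
from .pairing import AlignParams
from .spectra import (
    NORM_WINDOW,
    PEAK_WINDOW,
    SpectrumError,
    difference,
    difference_extrema,
    lambda_max,
    normalize,
    read_spectrum,
    write_spectrum,
)
from .structure_io import (
    DomainScheme,
    StructureError,
    StructureModel,
    apply_transform,
    load_config,
    read_structure,
    scheme_from_config,
)

__all__ = ["RunConfig", "run_compare", "run_spectra"]

logger = logging.getLogger(__name__)

REPORT_VERSION = "phytogeom-report-v1"


@dataclass
class RunConfig:
    reference: str = ""
    comparisons: list[str] = field(default_factory=list)
    scheme: DomainScheme | None = None
    align: AlignParams = field(default_factory=AlignParams)
    cutoff: float = 5.0
    spectra_jobs: list[dict] = field(default_factory=list)
    out_dir: Path = Path(".")
    symmetry: object = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("rejection cutoff must be positive")
        self.out_dir = Path(self.out_dir)
        outputs = {str(self.out_dir / "geometry.tsv"), str(self.out_dir / "spectra_summary.tsv")}
        for p in [self.reference] + list(self.comparisons):
            if p and str(p) in outputs:
                raise ValueError(f"input path {p} collides with an output path")

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path | None = None, seed: int = 0) -> "RunConfig":
        cfg = load_config(path)
        base = Path(path).parent
        align_cfg = cfg.get("align", {})

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        jobs = []
        for job in cfg.get("spectra_jobs", []):
            if "dark" not in job or "illuminated" not in job:
                raise ValueError(f"spectra job {job.get('name', '?')} needs dark and illuminated paths")
            jobs.append(
                {
                    "name": job.get("name", Path(job["dark"]).stem),
                    "dark": str(resolve(job["dark"])),
                    "illuminated": str(resolve(job["illuminated"])),
                }
            )
        rc = cls(
            reference=str(resolve(cfg["reference"])) if cfg.get("reference") else "",
            comparisons=[str(resolve(p)) for p in cfg.get("comparisons", [])],
            scheme=scheme_from_config(cfg),
            align=AlignParams(
                matrix=align_cfg.get("matrix", "BLOSUM62"),
                gap_open=float(align_cfg.get("gap_open", 10.0)),
                gap_extend=float(align_cfg.get("gap_extend", 1.0)),
            ),
            cutoff=float(cfg.get("cutoff", 5.0)),
            spectra_jobs=jobs,
            out_dir=Path(out_dir) if out_dir is not None else Path(cfg.get("out_dir", ".")),
            seed=seed,
        )
        rc.symmetry = cfg.get("symmetry")
        return rc


def _load_model(path: str, config: RunConfig) -> StructureModel:
    model = read_structure(path)
    # monomeric asymmetric unit + user-supplied symmetry operator -> dimer
    if config.symmetry is not None and len(model.chains) == 1:
        (cid, residues), = model.chains.items()
        mate = apply_transform(model, config.symmetry)
        mate_id = "B" if cid != "B" else "C"
        model.chains[mate_id] = [
            type(r)(r.number, r.insertion_code, r.name,
                    [a for a in r.atoms], r.het_flag)
            for r in mate.chains[cid]
        ]
    return model


def run_compare(config: RunConfig) -> tuple[pd.DataFrame, int]:
    """Geometry TSV for reference vs comparisons; returns (table, n_failures)."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    scheme = config.scheme
    if scheme is None:
        raise ValueError("compare needs a domain scheme")
    reference = _load_model(config.reference, config)
    comparisons = []
    failed_paths = []
    for p in config.comparisons:
        try:
            comparisons.append(_load_model(p, config))
        except StructureError as exc:
            logger.error("skipping %s: %s", p, exc)
            failed_paths.append((p, str(exc)))
    table = geometry_table(
        reference, comparisons, scheme,
        cutoff=config.cutoff, params=config.align, include_reference_row=True,
    )
    for p, msg in failed_paths:
        table.loc[len(table)] = {
            **{c: "" for c in table.columns},
            "structure": Path(p).stem,
            "flags": f"load: {msg}",
        }
    out = config.out_dir / "geometry.tsv"
    with open(out, "w") as fh:
        fh.write(f"# {REPORT_VERSION}\n")
        table.to_csv(fh, sep="\t", index=False)
    n_failures = len(failed_paths) + int((table["flags"] != "").sum())
    logger.info("wrote %s (%d rows, %d flagged)", out, len(table), n_failures)
    return table, n_failures


def run_spectra(config: RunConfig) -> tuple[pd.DataFrame, int]:
    """Normalize, difference and summarize each dark/illuminated spectra job."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    failures = 0
    for job in config.spectra_jobs:
        name = job["name"]
        row = {
            "sample": name, "lambda_max_dark_nm": "", "lambda_max_illuminated_nm": "",
            "diff_pos_nm": "", "diff_pos": "", "diff_neg_nm": "", "diff_neg": "", "flags": "",
        }
        try:
            dark = normalize(read_spectrum(job["dark"], f"{name} dark"))
            illum = normalize(read_spectrum(job["illuminated"], f"{name} illuminated"))
            diff = difference(illum, dark)
            write_spectrum(dark, config.out_dir / f"{name}_dark_norm.csv")
            write_spectrum(illum, config.out_dir / f"{name}_illuminated_norm.csv")
            write_spectrum(diff, config.out_dir / f"{name}_difference.csv")
            sm_dark = lambda_max(dark)
            sm_illum = lambda_max(illum)
            (pos_wl, pos_v), (neg_wl, neg_v) = difference_extrema(diff)
            flags = list(dict.fromkeys(sm_dark.flags + sm_illum.flags))
            if max(abs(pos_v), abs(neg_v)) < 1e-3:
                flags.append("no photoconversion")
            row.update(
                lambda_max_dark_nm=f"{sm_dark.lambda_max:.1f}",
                lambda_max_illuminated_nm=f"{sm_illum.lambda_max:.1f}",
                diff_pos_nm=f"{pos_wl:.1f}", diff_pos=f"{pos_v:.4f}",
                diff_neg_nm=f"{neg_wl:.1f}", diff_neg=f"{neg_v:.4f}",
                flags=";".join(flags),
            )
        except (SpectrumError, OSError) as exc:
            row["flags"] = f"error: {exc}"
            failures += 1
        rows.append(row)
    table = pd.DataFrame(rows)
    out = config.out_dir / "spectra_summary.tsv"
    with open(out, "w") as fh:
        fh.write(f"# {REPORT_VERSION}\n")
        table.to_csv(fh, sep="\t", index=False)
    logger.info("wrote %s (%d jobs, %d failed)", out, len(rows), failures)
    return table, failures
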