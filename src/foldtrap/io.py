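"""Readers, writers, configuration and the pipeline driver.

Conventions: residue indexing is 1-based inclusive everywhere (PDB
convention); distances are Å; kinetics time is minutes; trajectory time is
frames.  Every JSON artifact carries a provenance block (package version,
config hash, seed) so identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import biotite.structure as struc
import numpy as np
import pandas as pd
import yaml
from biotite.structure.io.pdb import PDBFile

from . import __version__
from .kinetics import RefoldingTimeCourse, normalize
from .topology import CalphaStructure

__all__ = [
    "read_calpha_pdb",
    "write_calpha_pdb",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_contacts_csv",
    "write_contacts_csv",
    "read_peptides_tsv",
    "write_peptides_tsv",
    "PipelineConfig",
    "run_pipeline",
]


def read_calpha_pdb(path, model: int = 1, chain: str | None = None,
                    synthetic: bool = False) -> CalphaStructure:
    """Extract the Cα trace of one chain from a PDB file.

    Model 1 and the first chain are used by default; alternate locations
    other than 'A' are dropped; insertion codes are rejected.  Residue
    numbering is preserved as-is — gaps are kept, never renumbered.
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=model, altloc="first")
    ca = atoms[atoms.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValueError(f"no Cα atoms in {path}")
    if chain is None:
        chain = ca.chain_id[0]
    ca = ca[ca.chain_id == chain]
    if ca.array_length() == 0:
        raise ValueError(f"chain {chain!r} has no Cα atoms")
    if np.any(ca.ins_code != ""):
        raise ValueError("insertion codes are not supported; "
                         "renumber the structure first")
    return CalphaStructure(coords=ca.coord, residue_ids=ca.res_id,
                           synthetic=synthetic, label=Path(path).stem)


def write_calpha_pdb(structure: CalphaStructure, path,
                     residue_names=None) -> None:
    """Write one CA atom per residue, single chain A."""
    n = structure.n_res
    atoms = struc.AtomArray(n)
    atoms.coord = structure.coords
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = structure.residue_ids
    atoms.res_name = (np.asarray(residue_names) if residue_names is not None
                      else np.full(n, "GLY"))
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_timecourse_csv(path, error_default: float | None = None,
                        label: str | None = None) -> RefoldingTimeCourse:
    """CSV columns: time_min, percent_refolded[, error] (percent units)."""
    df = pd.read_csv(path)
    required = {"time_min", "percent_refolded"}
    if not required.issubset(df.columns):
        raise ValueError(f"time-course CSV needs columns {sorted(required)}")
    error = df["error"].to_numpy() if "error" in df.columns else None
    tc = normalize(df["percent_refolded"].to_numpy(),
                   df["time_min"].to_numpy(), error=error,
                   label=label or Path(path).stem)
    if tc.sigma is None and error_default is not None:
        tc.sigma = np.full(len(tc.t), error_default)
    return tc


def write_timecourse_csv(tc: RefoldingTimeCourse, path) -> None:
    df = pd.DataFrame({"time_min": tc.t,
                       "percent_refolded": 100.0 * (1.0 - tc.p_nn)})
    if tc.sigma is not None:
        df["error"] = 100.0 * tc.sigma
    df.to_csv(path, index=False)


def read_contacts_csv(path) -> pd.DataFrame:
    """CSV columns: frame, contacts."""
    df = pd.read_csv(path)
    if not {"frame", "contacts"}.issubset(df.columns):
        raise ValueError("contacts CSV needs columns frame, contacts")
    return df


def write_contacts_csv(contacts, path) -> None:
    pd.DataFrame({"frame": np.arange(len(contacts)),
                  "contacts": np.asarray(contacts)}).to_csv(path, index=False)


_PEPTIDE_COLS = ["protein", "start", "end", "cut_site", "log2_ratio",
                 "timepoint", "significant"]


def read_peptides_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_PEPTIDE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"peptide TSV missing columns {sorted(missing)}")
    return df


def write_peptides_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=_PEPTIDE_COLS)


# ---------------------------------------------------------------------------
# pipeline driver


_KNOWN_STAGE_KEYS = {
    "refolding": {"timecourse_csv", "error_default"},
    "kd": {"contacts_csv", "threshold", "radius_A"},
    "entangle": {"frame_pdb", "native_pdb", "cutoff", "min_separation",
                 "tolerance_factor"},
    "synthetic": {"kind", "params"},
}
_KNOWN_TOP_KEYS = {"stages", "seed", "output_dir"} | set(_KNOWN_STAGE_KEYS)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Unknown keys are rejected by name; every random operation receives an
    explicit seed derived from the top-level one.
    """

    stages: list
    seed: int = 0
    output_dir: str = "."
    sections: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        stages = raw.get("stages")
        if not stages:
            raise ValueError("config must list at least one stage")
        for stage in stages:
            if stage not in _KNOWN_STAGE_KEYS:
                raise ValueError(f"unknown stage: {stage}")
            section = raw.get(stage, {})
            bad = set(section) - _KNOWN_STAGE_KEYS[stage]
            if bad:
                raise ValueError(
                    f"unknown key(s) in section {stage!r}: {sorted(bad)}")
        return cls(stages=list(stages), seed=int(raw.get("seed", 0)),
                   output_dir=str(raw.get("output_dir", ".")),
                   sections={s: raw.get(s, {}) for s in stages})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        blob = json.dumps({"stages": self.stages, "seed": self.seed,
                           "sections": self.sections}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> dict:
    return {"package": "foldtrap", "version": __version__,
            "config_hash": config.digest(), "seed": config.seed}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in order and write JSON reports.

    Each stage writes ``<output_dir>/<stage>.json`` with a provenance
    block; the bundle of all stage reports is returned.  Identical
    configs produce byte-identical outputs.
    """
    from . import binding, kinetics, topology  # local to avoid cycles

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # validate dependencies / inputs before any computation
    for stage in config.stages:
        section = config.sections.get(stage, {})
        for key in ("timecourse_csv", "contacts_csv", "frame_pdb",
                    "native_pdb"):
            if key in section and not Path(section[key]).exists():
                raise FileNotFoundError(
                    f"stage {stage!r} input missing: {section[key]}")

    bundle = {}
    for stage in config.stages:
        section = config.sections.get(stage, {})
        if stage == "refolding":
            tc = read_timecourse_csv(section["timecourse_csv"],
                                     error_default=section.get(
                                         "error_default", 0.01))
            fit = kinetics.fit_biexponential(tc)
            kinetics.k2_bounds(tc, fit)
            report = {"a0": fit.a0, "a1": fit.a1, "k1": fit.k1,
                      "k2": fit.k2, "k2_flag": fit.k2_flag,
                      "k2_upper": fit.k2_upper, "k2_lower": fit.k2_lower,
                      "sse": fit.sse,
                      "measurability_limit":
                          kinetics.measurability_limit(tc.duration)}
        elif stage == "kd":
            df = read_contacts_csv(section["contacts_csv"])
            contacts = df["contacts"].to_numpy()
            threshold = section.get("threshold") or \
                binding.suggest_threshold(contacts)
            _, p_complex = binding.classify_bound(contacts, threshold)
            volume = binding.sphere_volume(section.get("radius_A", 160.0))
            report = {"threshold": int(threshold), "p_complex": p_complex,
                      "volume_A3": volume,
                      "kd_molar": binding.kd(p_complex, volume)
                      if 0 < p_complex < 1 else None}
        elif stage == "entangle":
            native = read_calpha_pdb(section["native_pdb"], synthetic=True)
            frame = read_calpha_pdb(section["frame_pdb"], synthetic=True)
            cmap = topology.native_contacts(
                native, cutoff=section.get("cutoff", 8.0),
                min_separation=section.get("min_separation", 4))
            g, records = topology.g_metric(
                frame, native, cmap,
                tolerance_factor=section.get("tolerance_factor", 1.2))
            report = {"G": g, "n_native_contacts": len(cmap),
                      "n_changed": len(records),
                      "records": [asdict(r) for r in records]}
        elif stage == "synthetic":
            from .synthetic import TimeCourseSpec, gen_timecourse
            params = dict(section.get("params", {}))
            params.setdefault("seed", config.seed)
            tc = gen_timecourse(TimeCourseSpec(**params))
            csv_path = out_dir / "synthetic_timecourse.csv"
            write_timecourse_csv(tc, csv_path)
            report = {"file": csv_path.name, "n_points": len(tc.t)}
        else:  # pragma: no cover - guarded by config validation
            raise ValueError(stage)
        report["provenance"] = _provenance(config)
        path = out_dir / f"{stage}.json"
        path.write_text(json.dumps(_jsonable(report), indent=2,
                                   sort_keys=True) + "\n")
        bundle[stage] = report
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
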