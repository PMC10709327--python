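"""End-to-end orchestration: predict -> chemistry -> match -> quantify.

A :class:`PipelineConfig` carries every file path, tolerance and
prediction parameter; :func:`run_discovery` executes the stages in order
and writes each stage's table plus a manifest sufficient to reproduce
the run bit-for-bit. Stage outputs are identical to calling the stage
functions individually with the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .chemistry import CAPPED_MODS, ModificationSet, build_transition_list, fragment_ions, precursor_ion, transitions_to_frame
from .matching import Ms1Feature, StandardCurve, TransitionTrace, detect_peptide, fit_standard_curve
from .secretome import predict_proteome, predictions_to_frame, read_fasta

__all__ = ["PipelineConfig", "run_discovery"]


@dataclass
class PipelineConfig:
    """All knobs for a discovery run; defaults mirror the printed workflow
    tolerances (20 ppm, 1 min co-elution, S/N > 2.5, 0.5 Da daughter tol)."""

    fasta: str = ""
    features_csv: str | None = None
    traces_csv: str | None = None
    curve_csv: str | None = None
    expected_rt_csv: str | None = None

    ppm_tol: float = 20.0
    rt_tol_min: float = 1.0
    sn_threshold: float = 2.5
    mrm_rt_tol_min: float = 0.2
    msms_tol_da: float = 0.5

    max_length: int = 20
    min_length: int = 2
    nterm_residue: str = "Q"
    exclude_signal_peptide: bool = False

    pyroglu_from_gln: bool = True
    c_amide: bool = True
    carbamidomethyl_cys: bool = False

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ppm_tol", "rt_tol_min", "sn_threshold", "mrm_rt_tol_min", "msms_tol_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def mods(self) -> ModificationSet:
        return ModificationSet(
            pyroglu_from_gln=self.pyroglu_from_gln,
            c_amide=self.c_amide,
            carbamidomethyl_cys=self.carbamidomethyl_cys,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _load_traces(path: str) -> dict[str, TransitionTrace]:
    df = pd.read_csv(path)
    out: dict[str, TransitionTrace] = {}
    for compound, grp in df.groupby("compound"):
        grp = grp.sort_values("time_min")
        out[compound] = TransitionTrace.from_arrays(
            compound, grp["time_min"].to_list(), grp["intensity"].to_list(), 0.0
        )
    return out


def run_discovery(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every configured stage and write a reproducible run directory.

    Always writes predictions and MRM transitions; detection/quantification
    run only when a feature table (and per-compound standard RTs) are
    configured. Returns the run directory path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = read_fasta(config.fasta)
    candidates = predict_proteome(
        records,
        max_length=config.max_length,
        min_length=config.min_length,
        nterm_residue=config.nterm_residue,
        exclude_signal_peptide=config.exclude_signal_peptide,
    )
    preds = predictions_to_frame(candidates)
    preds.to_csv(out / "predictions.tsv", sep="\t", index=False)

    transitions, flagged = build_transition_list(candidates, mods=config.mods)
    transitions_to_frame(transitions).to_csv(out / "transitions.csv", index=False)

    counts = {
        "proteins": len(records),
        "candidates": len(candidates),
        "precursors_with_candidates": preds["accession"].nunique() if len(preds) else 0,
        "transitions": len(transitions),
        "flagged_no_transition": len(flagged),
    }

    if config.features_csv:
        feats = pd.read_csv(config.features_csv)
        features = [
            Ms1Feature(r.mz, r.rt_min, r.area, getattr(r, "sample", ""))
            for r in feats.itertuples()
        ]
        expected_rt: dict[str, float] = {}
        if config.expected_rt_csv:
            rt_df = pd.read_csv(config.expected_rt_csv)
            expected_rt = dict(zip(rt_df["compound"], rt_df["rt_min"]))
        traces = _load_traces(config.traces_csv) if config.traces_csv else {}
        curve: StandardCurve | None = None
        if config.curve_csv:
            cdf = pd.read_csv(config.curve_csv)
            curve = fit_standard_curve(cdf["conc_nM"], cdf["area"])

        rows = []
        for cand in candidates:
            compound = cand.capped_notation
            ion = precursor_ion(cand.core_sequence, config.mods, charge=1)
            rt = expected_rt.get(compound)
            trace = traces.get(compound)
            if trace is not None and rt is not None:
                trace = dataclasses.replace(trace, expected_rt=rt)
            res = detect_peptide(
                compound,
                ion.mz,
                rt,
                features,
                trace=trace,
                theoretical_fragments=fragment_ions(cand.core_sequence, config.mods),
                curve=curve,
                ppm_tol=config.ppm_tol,
                rt_tol_min=config.rt_tol_min,
                sn_threshold=config.sn_threshold,
                mrm_rt_tol_min=config.mrm_rt_tol_min,
                msms_tol_da=config.msms_tol_da,
            )
            rows.append(
                (
                    compound,
                    cand.precursor_accession,
                    ion.mz,
                    res.ms1_matched,
                    res.ms1_ppm_error,
                    res.mrm_evaluated,
                    res.mrm_validated,
                    res.mrm_sn,
                    res.concentration_nM,
                )
            )
        pd.DataFrame(
            rows,
            columns=[
                "compound",
                "accession",
                "theoretical_mz",
                "ms1_matched",
                "ms1_ppm_error",
                "mrm_evaluated",
                "mrm_validated",
                "mrm_sn",
                "concentration_nM",
            ],
        ).to_csv(out / "detections.tsv", sep="\t", index=False)
        det = pd.read_csv(out / "detections.tsv", sep="\t")
        counts["ms1_matched"] = int(det["ms1_matched"].sum())
        counts["mrm_validated"] = int(det["mrm_validated"].sum())

    manifest = {
        "config": dataclasses.asdict(config),
        "counts": counts,
        "versions": {"cappedpep": __version__, "python": platform.python_version()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
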