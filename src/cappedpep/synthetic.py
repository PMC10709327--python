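"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emits the same file formats the corresponding analysis
stage consumes, together with a truth record from which the planted
signal is exactly recoverable. Backgrounds are rejection-sampled so that
synthetic proteomes contain no unplanned capped-peptide candidates,
making planted counts exact; MS features/traces use Gaussian ppm jitter,
MAD-calibrated baselines and Gaussian elution peaks; quantification
tables use log-normal noise around condition means.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemistry import CAPPED_MODS, precursor_ion
from .secretome import CappedPeptideCandidate, ProteinRecord

__all__ = [
    "SyntheticTruth",
    "make_proteome",
    "make_ms1_and_traces",
    "make_standard_curve",
    "make_quant_experiment",
    "make_pharm_data",
]

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticTruth:
    seed: int
    candidates: list[CappedPeptideCandidate] = field(default_factory=list)
    features: pd.DataFrame | None = None
    traces: pd.DataFrame | None = None
    expected_rt: dict[str, float] = field(default_factory=dict)
    sn_levels: dict[str, float] = field(default_factory=dict)
    concentrations: dict[str, float] = field(default_factory=dict)
    fold_changes: dict[str, float] = field(default_factory=dict)
    params: dict[str, float] = field(default_factory=dict)


def _count_candidates(seq: str, max_length: int = 20, min_length: int = 2) -> int:
    """Independent brute count of (Q, G[KR]R) pairs within the length window."""
    count = 0
    for m in re.finditer(r"(?=(G[KR]R))", seq):
        g = m.start() + 1  # 1-based motif position
        for q in range(max(1, g - max_length), g - min_length + 1):
            if seq[q - 1] == "Q":
                count += 1
    return count


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = _ALPHABET) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _clean_background(rng: np.random.Generator, length: int, max_tries: int = 200) -> str:
    for _ in range(max_tries):
        s = _random_seq(rng, length)
        if _count_candidates(s) == 0:
            return s
    raise RuntimeError("could not sample a candidate-free background sequence")


def make_proteome(
    n_proteins: int,
    n_planted: int,
    seed: int,
    decoys: bool = True,
    seq_length: int = 300,
    planted_length_range: tuple[int, int] = (3, 20),
    planted_contexts: Sequence[str] = (),
    species: str = "synthetic",
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Synthetic secretome with exactly ``n_planted`` capped candidates.

    One compliant (Q, G[KR]R) pair is planted per chosen protein at a
    recorded coordinate; the rest of each sequence is rejection-sampled
    to be free of accidental candidates. With ``decoys``, three decoy
    proteins are appended that must yield no candidates: a Q at distance
    21 from its motif, a GKK near-motif, and a candidate span containing
    an ambiguous X. ``planted_contexts`` lets callers plant literal
    sequence contexts (e.g. a known prohormone cleavage region) instead
    of random ones.
    """
    if n_planted > n_proteins:
        raise ValueError("cannot plant more candidates than proteins")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    records: list[ProteinRecord] = []

    contexts = list(planted_contexts)
    for i in range(n_proteins):
        acc = f"SYN{i:04d}"
        if i < n_planted:
            if contexts:
                insert = contexts.pop(0)
            else:
                length = int(rng.integers(*planted_length_range, endpoint=True))
                body = _random_seq(rng, length - 1, _ALPHABET.replace("Q", ""))
                motif = "G" + rng.choice(["K", "R"]) + "R"
                insert = "Q" + body + motif
            for _ in range(200):
                pre_len = int(rng.integers(30, seq_length // 2))
                post_len = int(rng.integers(30, seq_length // 2))
                seq = (
                    _clean_background(rng, pre_len)
                    + insert
                    + _clean_background(rng, post_len)
                )
                if _count_candidates(seq) == _count_candidates(insert):
                    break
            else:
                raise RuntimeError("could not embed planted context cleanly")
            # record every candidate the literal insert itself implies
            for m in re.finditer(r"(?=(G[KR]R))", insert):
                g_local = m.start() + 1
                for q_local in range(max(1, g_local - 20), g_local - 1):
                    if insert[q_local - 1] != "Q":
                        continue
                    start = pre_len + q_local
                    motif_pos = pre_len + g_local
                    truth.candidates.append(
                        CappedPeptideCandidate(
                            precursor_accession=acc,
                            start=start,
                            end=motif_pos - 1,
                            core_sequence=seq[start - 1 : motif_pos - 1],
                            motif=seq[motif_pos - 1 : motif_pos + 2],
                            motif_position=motif_pos,
                            species=species,
                        )
                    )
        else:
            seq = _clean_background(rng, seq_length)
        records.append(ProteinRecord(accession=acc, sequence=seq, species=species))

    if decoys:
        bg = lambda n: _clean_background(rng, n)
        far_q = "Q" + _random_seq(rng, 20, _ALPHABET.replace("Q", "")) + "GKR"
        assert _count_candidates(far_q) == 0
        near_motif = "Q" + _random_seq(rng, 7, _ALPHABET.replace("Q", "")) + "GKK"
        with_x = "Q" + "AX" + _random_seq(rng, 5, _ALPHABET.replace("Q", "")) + "GRR"
        for j, insert in enumerate((far_q, near_motif, with_x)):
            records.append(
                ProteinRecord(
                    accession=f"DEC{j:02d}",
                    sequence=bg(60) + insert + bg(60),
                    species=species,
                )
            )
    return records, truth


def make_ms1_and_traces(
    truth: SyntheticTruth,
    seed: int,
    ppm_jitter_sigma: float = 3.0,
    baseline_sigma: float = 50.0,
    baseline_level: float = 500.0,
    sn_levels: Sequence[float] = (10.0,),
    decoy_ppm_offset: float = 25.0,
    rt_range: tuple[float, float] = (5.0, 30.0),
    peak_sigma_min: float = 0.15,
    sampling_dt_min: float = 0.01,
    response_slope: float = 1500.0,
    conc_range_nM: tuple[float, float] = (0.1, 100.0),
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """MS1 feature table and MRM traces for the planted candidates.

    Each planted candidate gets an MS1 feature at its theoretical [M+H]+
    with Gaussian ppm jitter, an assigned retention time, and an area on
    a linear response (area = slope x concentration) with concentrations
    log-uniform over ``conc_range_nM`` (the nanomolar span typical of
    circulating signaling peptides). A ppm-offset decoy feature is
    emitted per candidate. Traces carry a Gaussian elution peak whose
    apex height is ``sn`` x the MAD-calibrated baseline sigma, cycling
    through ``sn_levels``.
    """
    rng = np.random.default_rng(seed)
    feat_rows = []
    trace_rows = []
    for idx, cand in enumerate(truth.candidates):
        ion = precursor_ion(cand.core_sequence, CAPPED_MODS, charge=1)
        compound = cand.capped_notation
        rt = float(rng.uniform(*rt_range))
        conc = float(np.exp(rng.uniform(*np.log(conc_range_nM))))
        area = response_slope * conc
        mz_obs = ion.mz * (1 + rng.normal(0, ppm_jitter_sigma) * 1e-6)
        feat_rows.append((mz_obs, rt, area, "plasma"))
        feat_rows.append(
            (ion.mz * (1 + decoy_ppm_offset * 1e-6), rt, area * 0.5, "plasma")
        )
        truth.expected_rt[compound] = rt
        truth.concentrations[compound] = conc
        truth.params.setdefault("theoretical_mz:" + compound, ion.mz)

        sn = float(sn_levels[idx % len(sn_levels)])
        truth.sn_levels[compound] = sn
        t = np.arange(rt - 3.0, rt + 3.0, sampling_dt_min)
        noise = rng.normal(0, baseline_sigma, size=t.size)
        peak = sn * baseline_sigma * np.exp(-0.5 * ((t - rt) / peak_sigma_min) ** 2)
        y = np.clip(baseline_level + noise + peak, 0, None)
        for ti, yi in zip(t, y):
            trace_rows.append((compound, float(ti), float(yi)))

    features = pd.DataFrame(feat_rows, columns=["mz", "rt_min", "area", "sample"])
    traces = pd.DataFrame(trace_rows, columns=["compound", "time_min", "intensity"])
    truth.features = features
    truth.traces = traces
    truth.params["response_slope"] = response_slope
    truth.params["baseline_sigma"] = baseline_sigma
    return features, traces, truth


def make_standard_curve(
    seed: int,
    slope: float = 1500.0,
    intercept: float = 0.0,
    levels_nM: Sequence[float] = (0.1, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0),
    cv: float = 0.0,
) -> pd.DataFrame:
    """External standard curve: area = slope x conc + intercept, optional CV."""
    rng = np.random.default_rng(seed)
    conc = np.asarray(levels_nM, dtype=float)
    area = slope * conc + intercept
    if cv > 0:
        area = area * rng.lognormal(0, np.sqrt(np.log1p(cv**2)), size=conc.size)
    return pd.DataFrame({"conc_nM": conc, "area": area})


def make_quant_experiment(
    peptides: Sequence[str],
    conditions: Sequence[str],
    planted_fcs: Mapping[str, Mapping[str, float]] | Mapping[str, float],
    n_per_group: int,
    cv: float,
    seed: int,
    base_level: float = 1000.0,
) -> tuple[pd.DataFrame, dict[str, str], SyntheticTruth]:
    """Peptide x sample quantification table with planted fold changes.

    ``planted_fcs`` maps peptide -> fold change of every non-first
    condition relative to the first (control) condition, either as a flat
    mapping (one treated condition) or nested per condition. Noise is
    log-normal with the requested coefficient of variation, mean-corrected
    so group means are unbiased; cv = 0 reproduces the planted fold
    changes exactly.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    control = conditions[0]
    sigma = np.sqrt(np.log1p(cv**2))
    truth = SyntheticTruth(seed=seed)
    sample_condition: dict[str, str] = {}
    columns: list[str] = []
    for cond in conditions:
        for r in range(n_per_group):
            name = f"{cond}_{r+1}"
            columns.append(name)
            sample_condition[name] = cond

    def fc_for(pep: str, cond: str) -> float:
        if cond == control:
            return 1.0
        entry = planted_fcs.get(pep, 1.0)
        if isinstance(entry, Mapping):
            return float(entry.get(cond, 1.0))
        return float(entry)

    data = np.empty((len(peptides), len(columns)))
    for i, pep in enumerate(peptides):
        for j, col in enumerate(columns):
            mean = base_level * fc_for(pep, sample_condition[col])
            noise = rng.lognormal(-sigma**2 / 2, sigma) if cv > 0 else 1.0
            data[i, j] = mean * noise
        for cond in conditions[1:]:
            truth.fold_changes[f"{pep}|{cond}"] = fc_for(pep, cond)
    quant = pd.DataFrame(data, index=list(peptides), columns=columns)
    return quant, sample_condition, truth


def make_pharm_data(
    kind: str,
    seed: int,
    params: Mapping[str, float] | None = None,
    noise_cv: float = 0.0,
    n_replicates: int = 1,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Dose-response or decay series with recorded true parameters.

    ``kind="dose_response"``: 4PL over a log-spaced dose ladder
    (defaults: bottom 0, top 100, ec50 0.7e-9 M, hill 1; 8 levels from
    1e-12 to 1e-6 M). ``kind="decay"``: A*exp(-kt) sampled at
    0/20/40/60 min (defaults A=100, t_half 17.1 min), matching a plasma
    stability time course. Noise is multiplicative log-normal.
    """
    rng = np.random.default_rng(seed)
    p = dict(params or {})
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    truth = SyntheticTruth(seed=seed)

    def jitter(vals: np.ndarray) -> np.ndarray:
        if sigma == 0:
            return vals
        return vals * rng.lognormal(-sigma**2 / 2, sigma, size=vals.shape)

    if kind == "dose_response":
        bottom = p.get("bottom", 0.0)
        top = p.get("top", 100.0)
        ec50 = p.get("ec50", 0.7e-9)
        hill = p.get("hill", 1.0)
        doses = np.repeat(np.logspace(-12, -6, int(p.get("n_levels", 8))),
                          n_replicates)
        resp = bottom + (top - bottom) / (1 + (ec50 / doses) ** hill)
        df = pd.DataFrame({
            "dose_molar": doses,
            "response": jitter(resp),
            "replicate": np.tile(np.arange(n_replicates), len(doses) // n_replicates),
        })
        truth.params.update(bottom=bottom, top=top, ec50=ec50, hill=hill)
        return df, truth
    if kind == "decay":
        amplitude = p.get("amplitude", 100.0)
        t_half = p.get("t_half", 17.1)
        k = np.log(2) / t_half
        times = np.repeat(np.asarray(p.get("times", (0.0, 20.0, 40.0, 60.0))),
                          n_replicates)
        levels = amplitude * np.exp(-k * times)
        df = pd.DataFrame({
            "time_min": times,
            "level": jitter(levels),
            "replicate": np.tile(np.arange(n_replicates), len(times) // n_replicates),
        })
        truth.params.update(amplitude=amplitude, rate=k, t_half=t_half)
        return df, truth
    raise ValueError("kind must be 'dose_response' or 'decay'")
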