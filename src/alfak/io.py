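"""Readers, writers, karyotype construction from binned data, and fixtures.

The canonical interchange format is a long-format counts CSV with columns
``karyotype`` (dot-separated copy-number string), ``time_days``,
``passage`` and ``count``.  Landscape fits serialize to a YAML bundle
(anchor table, Matérn hyperparameters, region specification) plus a flat
karyotype -> fitness lookup-table CSV for the simulator's LUT mode.

Per-cell karyotypes are constructed from binned single-cell copy-number
matrices by taking, for each autosome, the modal integer copy number over
that cell's bins (ties resolved toward the cell's genome-wide median,
then lower).  Bin coordinates are 1-based inclusive; sex-chromosome and
other non-autosome bins are ignored.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .abm_sim import ABMConfig, GRFLandscape, SimResult, run_abm
from .freqfit import FitnessEstimate, LongitudinalCounts
from .karyospace import (
    N_AUTOSOMES,
    Karyotype,
    charted_region,
    format_karyotype,
    manhattan_distance,
    parse_karyotype,
)
from .landscape import FitnessLandscape, fit_kriging

__all__ = [
    "read_counts_csv",
    "write_counts_csv",
    "BinnedCNMatrix",
    "collapse_to_karyotype",
    "save_landscape",
    "load_landscape",
    "write_lut",
    "generate_fixture",
    "FIXTURE_SCENARIOS",
]

AUTOSOME_LABELS = [str(i) for i in range(1, N_AUTOSOMES + 1)]


def read_counts_csv(path) -> LongitudinalCounts:
    """Read a long-format counts CSV (karyotype, time_days, count[, passage])."""
    df = pd.read_csv(path)
    for col in ("karyotype", "time_days", "count"):
        if col not in df.columns:
            raise ValueError(f"counts CSV missing column {col!r}")
    times = np.array(sorted(df["time_days"].unique()), dtype=float)
    karyotypes = [parse_karyotype(s) for s in sorted(df["karyotype"].unique())]
    kindex = {format_karyotype(k): i for i, k in enumerate(karyotypes)}
    tindex = {t: j for j, t in enumerate(times)}
    counts = np.zeros((len(karyotypes), times.size), dtype=int)
    for _, row in df.iterrows():
        counts[kindex[str(row["karyotype"])], tindex[float(row["time_days"])]] += int(row["count"])
    return LongitudinalCounts(karyotypes, times, counts)


def write_counts_csv(data: LongitudinalCounts, path, passages: Optional[Sequence[int]] = None) -> None:
    """Write the long-format counts CSV; zero counts are omitted and rows
    follow a canonical (time, karyotype-string) order so that
    read -> write round-trips are byte-identical."""
    order = sorted(range(len(data.karyotypes)),
                   key=lambda i: format_karyotype(data.karyotypes[i]))
    rows = []
    for j, t in enumerate(data.times):
        for i in order:
            k = data.karyotypes[i]
            c = int(data.counts[i, j])
            if c > 0:
                rows.append(
                    {
                        "karyotype": format_karyotype(k),
                        "time_days": float(t),
                        "passage": int(passages[j]) if passages is not None else j,
                        "count": c,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class BinnedCNMatrix:
    """Cells x genomic-bins integer copy-number matrix with bin metadata.

    ``bin_chrom`` labels each bin's chromosome ("1".."22", "X", ...);
    ``bin_start``/``bin_end`` are 1-based inclusive coordinates.
    """

    matrix: np.ndarray  # cells x bins
    bin_chrom: List[str]
    bin_start: Optional[np.ndarray] = None
    bin_end: Optional[np.ndarray] = None
    cell_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.bin_chrom):
            raise ValueError("matrix columns must match bin metadata")
        if np.any(self.matrix < 0):
            raise ValueError("copy numbers must be >= 0")


def collapse_to_karyotype(m: BinnedCNMatrix, cell: int) -> Karyotype:
    """Collapse one cell's bins to a 22-autosome modal karyotype.

    Per autosome: the modal integer copy over its bins; modal ties go to
    the value closest to the cell's genome-wide (autosomal) median, then
    to the lower value.
    """
    row = m.matrix[cell]
    chrom = np.asarray(m.bin_chrom)
    auto_mask = np.isin(chrom, AUTOSOME_LABELS)
    gw_median = float(np.median(row[auto_mask])) if auto_mask.any() else 2.0
    out = []
    for lab in AUTOSOME_LABELS:
        vals = row[chrom == lab]
        if vals.size == 0:
            raise ValueError(f"cell {cell} has no bins on chromosome {lab}")
        uv, uc = np.unique(vals, return_counts=True)
        modes = uv[uc == uc.max()]
        out.append(int(min(modes, key=lambda v: (abs(v - gw_median), v))))
    return tuple(out)


def collapse_all(m: BinnedCNMatrix) -> List[Karyotype]:
    return [collapse_to_karyotype(m, c) for c in range(m.matrix.shape[0])]


# --------------------------------------------------------------------------
# landscape serialization


def save_landscape(land: FitnessLandscape, path) -> None:
    """Serialize a fitted landscape to a YAML bundle (anchors,
    hyperparameters, region spec).  The Kriging system is rebuilt on load."""
    frequent = [a for a in land.anchors if a.stage == "frequent"]
    doc = {
        "kernel_params": {
            "sigma2": land.sigma2, "rho": land.rho, "tau2": land.tau2, "nu": 1.5,
        },
        "metric": land.metric,
        "cv_score": land.cv,
        "anchors": [
            {
                "karyotype": format_karyotype(a.karyotype),
                "f": float(a.f),
                "stage": a.stage,
                "se": None if a.se is None else float(a.se),
                "parents": [format_karyotype(p) for p in a.parents],
            }
            for a in land.anchors
        ],
        "region": {
            "frequent": [format_karyotype(a.karyotype) for a in frequent],
            "radius": 2,
            "size": len(land.region),
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_landscape(path, max_copy: int = 8) -> FitnessLandscape:
    doc = yaml.safe_load(Path(path).read_text())
    anchors = [
        FitnessEstimate(
            parse_karyotype(a["karyotype"]), a["f"], stage=a["stage"],
            se=a.get("se"), parents=tuple(parse_karyotype(p) for p in a.get("parents", [])),
        )
        for a in doc["anchors"]
    ]
    kp = doc["kernel_params"]
    region = charted_region(
        [parse_karyotype(s) for s in doc["region"]["frequent"]],
        radius=doc["region"]["radius"], max_copy=max_copy,
    ) | {a.karyotype for a in anchors}
    land = fit_kriging(
        anchors, region=region, metric=doc.get("metric", "euclidean"),
        hyperparams=(kp["sigma2"], kp["rho"], kp["tau2"]),
    )
    land.cv = doc.get("cv_score")
    return land


def write_lut(land: FitnessLandscape, path) -> None:
    """Flat karyotype -> fitness table over the charted region."""
    lut = land.lut()
    pd.DataFrame(
        {"karyotype": [format_karyotype(k) for k in lut], "fitness": list(lut.values())}
    ).to_csv(path, index=False)


def read_lut(path) -> Dict[Karyotype, float]:
    df = pd.read_csv(path)
    return {parse_karyotype(s): float(f) for s, f in zip(df["karyotype"], df["fitness"])}


# --------------------------------------------------------------------------
# fixture generation


def _two_peak_fitness(
    peak1: Karyotype, peak2: Karyotype, h1: float, h2: float, w1: float, w2: float
):
    """Two exponential fitness peaks: a narrow high peak and a broad lower
    one, on the Manhattan metric."""

    def f(k: Sequence[int]) -> float:
        d1 = manhattan_distance(k, peak1)
        d2 = manhattan_distance(k, peak2)
        return h1 * np.exp(-d1 / w1) + h2 * np.exp(-d2 / w2)

    return f


FIXTURE_SCENARIOS = ("smooth-GRF", "rugged-GRF", "two-peak", "neutral", "wgd-mixture")

# Study-condition defaults for synthetic data: desk-scale passaging
# (capacity 1e4, 10% carried over, ~500 cells pseudo-sequenced per
# passage), per-copy missegregation probability 1e-3 per division, and a
# basal division rate of 1/day on which the GRF fitness (amplitude
# 0.3/day) rides.
_FIXTURE_ABM = dict(p=1e-3, Nmax=10_000, dilution=0.1, dt=0.1, duration=300.0,
                    sample_size=500, basal_rate=1.0)
_GRF_AMPLITUDE = 0.3


def fixture_landscape(scenario: str, seed: int):
    """Ground-truth fitness source for a named scenario."""
    if scenario == "smooth-GRF":
        return GRFLandscape(wavelength=2.0, amplitude=_GRF_AMPLITUDE, seed=seed)
    if scenario == "rugged-GRF":
        return GRFLandscape(wavelength=0.5, amplitude=_GRF_AMPLITUDE, seed=seed)
    if scenario == "neutral":
        return lambda k: 0.0
    if scenario == "two-peak":
        near = (2,) * N_AUTOSOMES
        far = list(near)
        for c in range(4):
            far[c] = 3
        return _two_peak_fitness(tuple(far), near, h1=0.5, h2=0.35, w1=0.8, w2=4.0)
    if scenario == "wgd-mixture":
        return GRFLandscape(wavelength=2.0, amplitude=_GRF_AMPLITUDE, seed=seed)
    raise ValueError(f"unknown scenario {scenario!r}; valid: {FIXTURE_SCENARIOS}")


def generate_fixture(
    scenario: str,
    seed: int,
    outdir,
    n_passages: int = 8,
    abm_overrides: Optional[dict] = None,
) -> SimResult:
    """Simulate a named scenario and write counts + ground-truth tables.

    Writes ``counts.csv`` (long format) and ``truth.csv`` (karyotype,
    fitness for every observed karyotype) under ``outdir``; byte-identical
    for a fixed seed.  The wgd-mixture scenario founds the population with
    a 1:1 mix of near-diploid and near-tetraploid clones.
    """
    if scenario not in FIXTURE_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; valid: {FIXTURE_SCENARIOS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {**_FIXTURE_ABM, **(abm_overrides or {}), "seed": seed}
    cfg = ABMConfig(**params)
    fitness = fixture_landscape(scenario, seed)
    initial = None
    if scenario == "wgd-mixture":
        n0 = int(cfg.Nmax * cfg.dilution)
        initial = {(2,) * N_AUTOSOMES: n0 // 2, (4,) * N_AUTOSOMES: n0 - n0 // 2}
    res = run_abm(cfg, fitness, initial=initial, n_passages=n_passages)
    counts = res.to_counts()
    write_counts_csv(counts, outdir / "counts.csv")
    pd.DataFrame(
        {
            "karyotype": [format_karyotype(k) for k in sorted(res.truth)],
            "fitness": [res.truth[k] for k in sorted(res.truth)],
        }
    ).to_csv(outdir / "truth.csv", index=False)
    return res


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance logs."""
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
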