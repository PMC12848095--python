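"""File I/O and the named synthetic fixture generator.

Plain-text formats throughout: longitudinal counts are CSV with columns
``time_days, karyotype, count`` (karyotypes in the dot-separated string
form), landscapes are a CSV look-up table plus a JSON sidecar carrying the
CV score and configuration echo.

The fixture generator couples the GRF landscape generator and the ABM into
named, seed-reproducible scenarios used by the test-suite and the examples.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .abm import LUTLandscape, SimConfig, run_simulation
from .grf import GRFLandscape, generate_grf
from .inference import FittedLandscape, LongitudinalCounts
from .karyotype import (
    DIPLOID,
    charted_region,
    format_karyotype,
    manhattan_distance,
    parse_karyotype,
)

FORMAT_VERSION = 1
_SOURCES = {"frequent", "neighbor", "interpolated"}


def read_counts(path) -> LongitudinalCounts:
    """Read a longitudinal count table (CSV with a header).

    Duplicate (time, karyotype) rows are summed with a warning; malformed
    karyotypes or negative counts raise with the offending row number
    (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    required = {"time_days", "karyotype", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts file must have columns {sorted(required)}")
    tables: dict = {}
    seen = set()
    dup = False
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            k = parse_karyotype(str(row.karyotype))
        except ValueError as e:
            raise ValueError(f"row {row_no}: {e}") from None
        c = row.count
        if c < 0 or c != int(c):
            raise ValueError(f"row {row_no}: count must be a non-negative integer")
        t = float(row.time_days)
        if (t, k) in seen:
            dup = True
        seen.add((t, k))
        tables.setdefault(t, {})
        tables[t][k] = tables[t].get(k, 0) + int(c)
    if dup:
        warnings.warn("duplicate (time, karyotype) rows summed", UserWarning)
    times = sorted(tables)
    return LongitudinalCounts(times=times, tables=[tables[t] for t in times])


def write_counts(counts: LongitudinalCounts, path) -> None:
    rows = []
    for t, tab in zip(counts.times, counts.tables):
        for k in sorted(tab):
            rows.append((t, format_karyotype(k), tab[k]))
    pd.DataFrame(rows, columns=["time_days", "karyotype", "count"]).to_csv(
        path, index=False
    )


def _sidecar_path(csv_path) -> Path:
    p = Path(csv_path)
    return p.with_suffix(p.suffix + ".json")


def write_landscape(landscape: FittedLandscape, path) -> None:
    """Write the LUT CSV (karyotype, mean_fitness, sd, source) + JSON sidecar."""
    rows = []
    for k in sorted(landscape.lut):
        rows.append(
            (
                format_karyotype(k),
                landscape.lut[k],
                landscape.lut_sd.get(k, float("nan")),
                landscape.source.get(k, "interpolated"),
            )
        )
    df = pd.DataFrame(rows, columns=["karyotype", "mean_fitness", "sd", "source"])
    df.to_csv(path, index=False)
    digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    sidecar = {
        "format_version": FORMAT_VERSION,
        "cv_score": landscape.cv_score,
        "n_frequent": len(landscape.frequent),
        "n_neighbors": len(landscape.neighbors),
        "config": asdict(landscape.config),
        "lut_sha256": digest,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


@dataclass
class LoadedLandscape:
    """A landscape LUT re-read from disk (no GP object)."""

    lut: dict
    lut_sd: dict
    source: dict
    cv_score: float
    meta: dict

    def as_lut(self, out_of_table: str = "lethal") -> LUTLandscape:
        return LUTLandscape(table=dict(self.lut), out_of_table=out_of_table)


def read_landscape(path) -> LoadedLandscape:
    """Read a LUT CSV written by :func:`write_landscape`.

    A missing sidecar loads the LUT with defaults and a warning; a sidecar
    format-version mismatch warns; an unknown source tag raises.
    """
    df = pd.read_csv(path)
    lut, sd, source = {}, {}, {}
    for row in df.itertuples(index=False):
        k = parse_karyotype(row.karyotype)
        if row.source not in _SOURCES:
            raise ValueError(f"unknown source tag: {row.source!r}")
        lut[k] = float(row.mean_fitness)
        sd[k] = float(row.sd)
        source[k] = row.source
    meta: dict = {}
    cv = float("nan")
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        if meta.get("format_version") != FORMAT_VERSION:
            warnings.warn(
                f"landscape sidecar format version {meta.get('format_version')} "
                f"differs from {FORMAT_VERSION}",
                UserWarning,
            )
        cv = float(meta.get("cv_score", float("nan")))
    else:
        warnings.warn("landscape sidecar missing; loading with defaults", UserWarning)
    return LoadedLandscape(lut=lut, lut_sd=sd, source=source, cv_score=cv, meta=meta)


# --------------------------------------------------------------------------
# fixtures


@dataclass
class Fixture:
    """In-memory synthetic dataset for one named scenario."""

    scenario: str
    seed: int
    counts: Optional[LongitudinalCounts]
    landscape: object  # GRFLandscape or LUTLandscape (the ground truth)
    manifest: dict
    held_out: Optional[dict] = None  # future sample (karyotype -> count)
    extra: dict = field(default_factory=dict)


SCENARIOS = ("smooth_grf", "rugged_grf", "two_clone", "flat_neutral", "two_peak_toy")

# Study conditions for the GRF benchmarking scenarios: founder fitness is
# calibrated to 1 division/day, fluctuations of 0.3/day around it, serial
# passaging 10^3 -> 10^4 cells with 500 cells sequenced per passage, and a
# per-copy missegregation probability of 7.5e-4 per division. Eight passages
# train the model; the ninth is held out for forecast validation.
_GRF_PARAMS = dict(
    n_basis=64,
    amplitude=0.3,
    founder_fitness=1.0,
    p=0.00075,
    N_max=10_000,
    n_seed=1_000,
    dt=0.1,
    sample_size=500,
    n_train_passages=8,
    n_future_passages=3,  # forecast horizon: the 3rd passage after training
)
_WAVELENGTHS = {"smooth_grf": 1.6, "rugged_grf": 0.4, "flat_neutral": 1.6}


def _grf_fixture(scenario: str, seed: int) -> Fixture:
    params = dict(_GRF_PARAMS)
    amplitude = 0.0 if scenario == "flat_neutral" else params["amplitude"]
    land = generate_grf(
        wavelength=_WAVELENGTHS[scenario],
        n_basis=params["n_basis"],
        amplitude=amplitude,
        seed=seed,
    ).with_founder_fitness(DIPLOID, params["founder_fitness"])
    n_samples = params["n_train_passages"] + 1  # t=0 counted in the train set
    n_future = params["n_future_passages"]
    cfg = SimConfig(
        p=params["p"],
        N_max=params["N_max"],
        n_seed=params["n_seed"],
        dt=params["dt"],
        t_end=300.0,
        founder=DIPLOID,
        sample_size=params["sample_size"],
        max_passages=n_samples + n_future - 1,
        seed=seed,
    )
    result = run_simulation(cfg, land)
    records = result.records[: n_samples + n_future]
    if len(records) < n_samples + n_future:
        raise RuntimeError(
            f"simulation yielded only {len(records)} samples (extinct={result.extinct})"
        )
    train = records[:n_samples]
    held_out = records[n_samples + n_future - 1]
    counts = LongitudinalCounts.from_records(train)
    manifest = {
        "scenario": scenario,
        "seed": seed,
        "grf": land.to_config(),
        "sim": {k: v for k, v in asdict(cfg).items() if k != "init_counts"},
        "held_out_time": held_out.time,
    }
    return Fixture(
        scenario=scenario,
        seed=seed,
        counts=counts,
        landscape=land,
        manifest=manifest,
        held_out=dict(held_out.sample),
    )


def _two_clone_fixture(seed: int) -> Fixture:
    k1 = DIPLOID
    k2 = (3,) + DIPLOID[1:]
    lut = LUTLandscape(table={k1: 0.5, k2: 0.6})
    cfg = SimConfig(
        p=0.0,
        N_max=10_000,
        n_seed=1_000,
        dt=0.05,
        t_end=100.0,
        init_counts={k1: 500, k2: 500},
        sample_size=500,
        max_passages=4,
        seed=seed,
    )
    result = run_simulation(cfg, lut)
    counts = LongitudinalCounts.from_records(result.records)
    manifest = {
        "scenario": "two_clone",
        "seed": seed,
        "lut": {format_karyotype(k): v for k, v in lut.table.items()},
        "sim": {k: v for k, v in asdict(cfg).items() if k != "init_counts"},
    }
    return Fixture(
        scenario="two_clone",
        seed=seed,
        counts=counts,
        landscape=lut,
        manifest=manifest,
    )


def two_peak_landscape() -> LUTLandscape:
    """An engineered error-threshold toy: a narrow high peak vs a broad plateau.

    Peak A is the diploid state at fitness 0.30/day surrounded by poor
    neighbors (0.05/day); peak B, six missegregations away, is a plateau
    where every karyotype within two steps has fitness 0.25/day. At low
    missegregation rates the single fittest state dominates; above a critical
    rate the quasispecies on the broad plateau takes over because its
    offspring remain fit.
    """
    kA = DIPLOID
    kB = (3,) * 6 + (2,) * 16
    region = charted_region({kA, kB}, radius=2)
    table = {}
    for k in sorted(region):
        if k == kA:
            table[k] = 0.30
        elif manhattan_distance(k, kB) <= 2:
            table[k] = 0.25
        else:
            table[k] = 0.05
    return LUTLandscape(table=table)


def _two_peak_fixture(seed: int) -> Fixture:
    lut = two_peak_landscape()
    kA = DIPLOID
    kB = (3,) * 6 + (2,) * 16
    manifest = {
        "scenario": "two_peak_toy",
        "seed": seed,
        "peak_narrow": format_karyotype(kA),
        "peak_plateau": format_karyotype(kB),
        "n_states": len(lut.table),
        "suggested_rates": [1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2, 1e-1],
    }
    return Fixture(
        scenario="two_peak_toy",
        seed=seed,
        counts=None,
        landscape=lut,
        manifest=manifest,
        extra={"peak_narrow": kA, "peak_plateau": kB},
    )


def generate_fixture(scenario: str, seed: int = 0, out_dir=None) -> Fixture:
    """Generate a named synthetic scenario; byte-reproducible from the seed.

    Scenarios: ``smooth_grf`` (lambda=1.6 GRF + ABM, 8 training passages and
    one held out), ``rugged_grf`` (lambda=0.4), ``two_clone`` (two-karyotype
    LUT, no missegregation), ``flat_neutral`` (zero-amplitude landscape),
    ``two_peak_toy`` (error-threshold LUT, no count data).

    With ``out_dir`` given, writes ``counts.csv``, ``manifest.json`` and, for
    scenarios with count data and a ground-truth landscape, a
    ``true_fitness.csv`` table for every karyotype appearing in the counts.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if scenario in ("smooth_grf", "rugged_grf", "flat_neutral"):
        fx = _grf_fixture(scenario, seed)
    elif scenario == "two_clone":
        fx = _two_clone_fixture(seed)
    else:
        fx = _two_peak_fixture(seed)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(fx.manifest, indent=2))
        if fx.counts is not None:
            write_counts(fx.counts, out / "counts.csv")
            rows = [
                (format_karyotype(k), fx.landscape.fitness(k))
                for k in sorted(fx.counts.karyotypes())
                if fx.landscape.fitness(k) is not None
            ]
            pd.DataFrame(rows, columns=["karyotype", "true_fitness"]).to_csv(
                out / "true_fitness.csv", index=False
            )
        if fx.held_out is not None:
            rows = [
                (format_karyotype(k), c) for k, c in sorted(fx.held_out.items())
            ]
            pd.DataFrame(rows, columns=["karyotype", "count"]).to_csv(
                out / "held_out_sample.csv", index=False
            )
    return fx
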