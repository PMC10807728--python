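"""Seeded synthetic studies, plain-text trace I/O and config handling.

The study generator emulates a frozen-glass pulsed-EPR study design:
mono- and biradical samples at ~50 uM, each measured with SIFTER, SIDRE and
variable-delay Hahn-echo experiments at several total trace lengths.  Two
built-in relaxation presets contrast the two commonly used radical classes:

* ``nitroxide-like``: shorter decoherence time, stronger dynamical
  decoupling (larger xi), as seen for aminoxyl labels in protonated glass;
* ``trityl-like``: longer decoherence, weaker decoupling, as seen for
  carbon-centred radicals.

Noise is additive white Gaussian on the echo-integrated amplitude with
sigma = max|amplitude| / SNR.  Everything is deterministic given the master
seed; every trace header records the seed and ground-truth parameters, so
any pipeline step can be re-run from the files alone.

Trace file format: ASCII, '#'-prefixed ``key: value`` header lines followed
by two numeric columns (t in us, amplitude).  Round-trips are bit-exact for
header values and full float precision (repr) for columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dipolar_model import DistanceDistribution
from .relaxation_models import (SidreSurfaceParams, StretchedExpParams,
                                evaluate_bt, sidre_trace)
from .signal_composition import (CompositionParams, compose_biradical,
                                 compose_monoradical)
from .trace import DipolarTrace

__all__ = [
    "RELAXATION_PRESETS",
    "SampleSpec",
    "StudyConfig",
    "StudyDataset",
    "default_study_config",
    "generate_study",
    "add_noise",
    "read_trace",
    "write_trace",
]

# weight, tau_d (us), beta; xi is the decoupling shape exponent
RELAXATION_PRESETS: dict[str, dict] = {
    "nitroxide-like": {"components": ((1.0, 3.5, 1.4),), "xi": 2.4},
    "trityl-like": {"components": ((1.0, 7.0, 1.0),), "xi": 1.6},
}


@dataclass(frozen=True)
class SampleSpec:
    """One synthetic sample: radical kind, distances, relaxation and depth."""

    name: str
    kind: str                      # "mono" | "bi"
    relaxation: str = "nitroxide-like"   # preset name
    concentration_um: float = 50.0
    r_mean_nm: float = 3.0         # bi only
    r_sigma_nm: float = 0.2        # bi only
    lam: float = 0.3               # modulation depth, bi only
    D: float = 0.02                # rad^2/us^2; explicit transfer-artefact amplitude

    def __post_init__(self) -> None:
        if self.kind not in ("mono", "bi"):
            raise ValueError("sample kind must be 'mono' or 'bi'")
        if self.relaxation not in RELAXATION_PRESETS:
            raise ValueError(f"unknown relaxation preset {self.relaxation!r}")

    def relaxation_models(self) -> tuple[list[StretchedExpParams], SidreSurfaceParams]:
        preset = RELAXATION_PRESETS[self.relaxation]
        comps = [StretchedExpParams(*c) for c in preset["components"]]
        return comps, SidreSurfaceParams(tuple(comps), preset["xi"])

    def distribution(self) -> DistanceDistribution | None:
        if self.kind == "mono":
            return None
        return DistanceDistribution.gaussian(self.r_mean_nm, self.r_sigma_nm)


@dataclass(frozen=True)
class StudyConfig:
    samples: tuple
    tau0_list_us: tuple = (1.5, 2.5, 3.5, 4.5)
    dt_us: float = 0.05
    snr: float = 50.0
    master_seed: int = 2023

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.tau0_list_us):
            raise ValueError("all tau0 must be positive")
        if not (self.snr > 0):
            raise ValueError("SNR must be positive")
        if self.dt_us <= 0:
            raise ValueError("grid step must be positive")


def default_study_config(snr: float = 50.0, master_seed: int = 2023) -> StudyConfig:
    """2 radical classes x {mono, bi} x 4 trace lengths, 50 uM."""
    samples = tuple(
        SampleSpec(name=f"{rad.split('-')[0]}_{kind}", kind=kind, relaxation=rad)
        for rad in ("nitroxide-like", "trityl-like")
        for kind in ("mono", "bi")
    )
    return StudyConfig(samples=samples, snr=snr, master_seed=master_seed)


@dataclass
class StudyEntry:
    sample: SampleSpec
    tau0: float
    sifter: DipolarTrace
    sidre: DipolarTrace
    hahn: DipolarTrace
    truth: dict


@dataclass
class StudyDataset:
    config: StudyConfig
    entries: list

    def write(self, directory) -> list:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for e in self.entries:
            for seq in ("sifter", "sidre", "hahn"):
                p = directory / f"{e.sample.name}_tau0_{e.tau0:g}_{seq}.dat"
                write_trace(getattr(e, seq), p)
                paths.append(p)
        (directory / "study_config.json").write_text(
            json.dumps(asdict(self.config), indent=2, default=list))
        return paths


def _trace_seed(master_seed: int, sample_idx: int, tau_idx: int, which: int) -> int:
    ss = np.random.SeedSequence([master_seed, sample_idx, tau_idx, which])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def generate_study(config: StudyConfig) -> StudyDataset:
    """Generate SIFTER + SIDRE + Hahn traces for every sample x trace length."""
    entries = []
    for si, sample in enumerate(config.samples):
        bt, bs = sample.relaxation_models()
        dist = sample.distribution()
        for ti, tau0 in enumerate(config.tau0_list_us):
            n_half = int(round(tau0 / config.dt_us))
            t = np.linspace(-tau0, tau0, 2 * n_half + 1)
            if sample.kind == "mono":
                sifter = compose_monoradical(bt, bs, sample.D, tau0, t)
                truth = {"kind": "mono", "D": sample.D}
            else:
                params = CompositionParams(lam=sample.lam, D=sample.D, tau0=tau0)
                sifter, breakdown = compose_biradical(
                    dist, bt, bs, params, t, return_breakdown=True)
                truth = {"kind": "bi", "D": sample.D, "lambda": sample.lam,
                         "r_mean_nm": sample.r_mean_nm, "r_sigma_nm": sample.r_sigma_nm,
                         "K": breakdown["K"], "breakdown": breakdown}
            sidre = sidre_trace(bs, tau0, t)
            tau_grid = np.linspace(config.dt_us, tau0, n_half)
            hahn = DipolarTrace(tau_grid, evaluate_bt(bt, tau_grid),
                                {"sequence": "hahn", "tau0": float(tau0)})
            common = {"sample": sample.name, "kind": sample.kind,
                      "relaxation": sample.relaxation,
                      "concentration_um": sample.concentration_um,
                      "snr": config.snr, "master_seed": config.master_seed}
            for which, (name, tr) in enumerate(
                    (("sifter", sifter), ("sidre", sidre), ("hahn", hahn))):
                truth[f"clean_{name}"] = tr.amplitude.copy()
                tr.metadata.update(common)
                seed = _trace_seed(config.master_seed, si, ti, which)
                noisy = add_noise(tr, config.snr, seed)
                tr.amplitude = noisy.amplitude
                tr.metadata.update(noisy.metadata)
            entries.append(StudyEntry(sample, float(tau0), sifter, sidre, hahn, truth))
    return StudyDataset(config, entries)


def add_noise(trace: DipolarTrace, snr: float, seed: int) -> DipolarTrace:
    """Additive white Gaussian noise, sigma = max|amplitude| / SNR."""
    if not (snr > 0):
        raise ValueError("SNR must be positive")
    if np.isinf(snr):
        return trace.copy_with(trace.amplitude.copy(), snr=snr)
    sigma = float(np.max(np.abs(trace.amplitude))) / snr
    rng = np.random.default_rng(seed)
    noisy = trace.amplitude + rng.normal(0.0, sigma, size=trace.amplitude.shape)
    return trace.copy_with(noisy, snr=snr, noise_seed=int(seed), noise_sigma=sigma)


# -- trace files -----------------------------------------------------------

_META_ORDER = ("sequence", "tau0", "sample", "kind", "relaxation",
               "concentration_um", "snr", "noise_seed", "noise_sigma",
               "master_seed", "lambda", "D", "K", "xi")


def write_trace(trace: DipolarTrace, path) -> Path:
    """ASCII trace file: '# key: value' header, two columns (t_us, amplitude)."""
    path = Path(path)
    lines = ["# siftersim trace v1", "# units: t=us amplitude=a.u."]
    meta = dict(trace.metadata)
    keys = [k for k in _META_ORDER if k in meta] + \
           sorted(k for k in meta if k not in _META_ORDER)
    for k in keys:
        v = meta[k]
        if isinstance(v, (dict, list, tuple, np.ndarray)):
            continue  # structured provenance stays in memory, not in headers
        lines.append(f"# {k}: {_fmt(v)}")
    for t, a in zip(trace.t_us, trace.amplitude):
        lines.append(f"{float(t)!r} {float(a)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_value(s: str):
    s = s.strip()
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def read_trace(path) -> DipolarTrace:
    """Read a trace file; legacy two-column files without header are accepted."""
    path = Path(path)
    meta: dict = {}
    t_vals, a_vals = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    if " " not in k.strip():
                        meta[k.strip()] = _parse_value(v)
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two numeric columns")
            try:
                t_vals.append(float(parts[0]))
                a_vals.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric row: {line!r}") from exc
    if not t_vals:
        raise ValueError(f"{path}: no data rows")
    if "sequence" not in meta:
        meta.setdefault("warnings", "headerless legacy file; sequence unknown")
    if meta.get("sequence") in ("sifter", "sidre") and "tau0" not in meta:
        raise ValueError(f"{path}: {meta['sequence']} trace lacks required tau0 header")
    return DipolarTrace(np.asarray(t_vals), np.asarray(a_vals), meta)
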