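"""Synthetic paired scar/normal miRNA microarray datasets with known truth.

The generator produces the statistical structure the downstream pipeline
assumes and every distortion it claims to correct. On the log2 scale the
true expression of miRNA g on the array of patient i, condition c, is

    L = mu_g + b_i + delta_g * 1[c = scar] + eps,

with per-patient random effect b_i ~ N(0, patient_sd^2), residual
eps ~ N(0, noise_sd^2), and a planted signed effect delta_g that is
nonzero only for a chosen subset of miRNAs (a configurable fraction of
them lowered in scar). The raw scanner intensity is then

    raw = (2^L + background_level) * 2^{f_a(L)},

where f_a is a smooth per-array polynomial bias curve with sup-norm at
most ``bias_amplitude`` on the observed intensity range — a
multiplicative, intensity-dependent distortion that MA-lowess
normalization is the appropriate remedy for.

Identical configurations (including the seed) yield bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from . import io


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model; defaults mirror the study design.

    Defaults of 513 miRNAs and 9 patients reproduce the shape of the
    original paired experiment (9 patients, scar + adjacent normal skin
    each, 513 analyzable probes).
    """

    n_mirnas: int = 513
    n_patients: int = 9
    n_true_de: int = 20
    frac_down: float = 0.75
    effect_log2: float = 1.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    patient_sd: float = 0.5
    noise_sd: float = 0.5
    background_level: float = 50.0
    bias_amplitude: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_mirnas < 1:
            raise ConfigurationError("n_mirnas must be a positive integer")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be a positive integer")
        if not 0 <= self.n_true_de <= self.n_mirnas:
            raise ConfigurationError(
                "n_true_de must lie in [0, n_mirnas]")
        if not 0.0 <= self.frac_down <= 1.0:
            raise ConfigurationError("frac_down must lie in [0, 1]")
        if self.effect_log2 <= 0:
            raise ConfigurationError("effect_log2 must be positive")
        if self.baseline_sd < 0:
            raise ConfigurationError("baseline_sd must be non-negative")
        if self.patient_sd < 0:
            raise ConfigurationError("patient_sd must be non-negative")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.background_level < 0:
            raise ConfigurationError("background_level must be non-negative")
        if self.bias_amplitude < 0:
            raise ConfigurationError("bias_amplitude must be non-negative")

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroundTruth:
    """Which miRNAs were planted as differential, and their signed effects."""

    de_ids: frozenset
    effect_per_id: dict
    seed: int | None = None

    def effect(self, mirna_id: str) -> float:
        """Signed log2 effect (scar - normal); 0 for non-planted miRNAs."""
        return self.effect_per_id.get(mirna_id, 0.0)


def _mirna_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"mir-{i + 1:0{width}d}" for i in range(n)]


def _bias_curve(log2_level: np.ndarray, coeffs: np.ndarray, lo: float,
                hi: float, amplitude: float) -> np.ndarray:
    """Smooth per-array bias f_a(L), sup-norm bounded by ``amplitude``.

    A degree-2 Chebyshev polynomial in L rescaled to [-1, 1]; dividing by
    the l1 norm of the coefficients bounds |f_a| <= amplitude there.
    """
    if amplitude == 0.0:
        return np.zeros_like(log2_level)
    span = hi - lo
    if span <= 0:
        return np.zeros_like(log2_level)
    z = np.clip(2.0 * (log2_level - lo) / span - 1.0, -1.0, 1.0)
    basis = np.stack([z, 2.0 * z * z - 1.0])
    norm = np.abs(coeffs).sum()
    if norm == 0:
        return np.zeros_like(log2_level)
    return amplitude * (coeffs @ basis.reshape(2, -1)).reshape(z.shape) / norm


def simulate_dataset(config: SimulationConfig):
    """Draw one paired dataset from the generative model.

    Returns
    -------
    matrix : DataFrame
        Raw non-negative intensities, miRNAs x arrays. Columns are
        ordered patient-major (``p1_scar, p1_normal, p2_scar, ...``).
    sheet : DataFrame
        Sample sheet with columns ``array_id, patient_id, condition``;
        each patient has exactly one scar and one normal array.
    truth : GroundTruth
        Planted differential miRNAs with their signed log2 effects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    mirnas = _mirna_ids(config.n_mirnas)
    patients = [f"p{i + 1}" for i in range(config.n_patients)]
    arrays, patient_of, is_scar = [], [], []
    for p in patients:
        for cond in ("scar", "normal"):
            arrays.append(f"{p}_{cond}")
            patient_of.append(p)
            is_scar.append(cond == "scar")
    is_scar = np.asarray(is_scar)

    mu = rng.normal(config.baseline_mean, config.baseline_sd,
                    size=config.n_mirnas)
    b = rng.normal(0.0, config.patient_sd, size=config.n_patients)

    delta = np.zeros(config.n_mirnas)
    de_idx = rng.choice(config.n_mirnas, size=config.n_true_de, replace=False)
    n_down = int(round(config.frac_down * config.n_true_de))
    signs = np.ones(config.n_true_de)
    signs[:n_down] = -1.0
    rng.shuffle(signs)
    delta[de_idx] = signs * config.effect_log2

    b_per_array = np.repeat(b, 2)
    eps = rng.normal(0.0, config.noise_sd,
                     size=(config.n_mirnas, len(arrays)))
    log2_true = (mu[:, None] + b_per_array[None, :]
                 + np.outer(delta, is_scar.astype(float)) + eps)

    raw = np.exp2(log2_true) + config.background_level
    if config.bias_amplitude > 0:
        lo, hi = float(log2_true.min()), float(log2_true.max())
        for a in range(len(arrays)):
            coeffs = rng.uniform(-1.0, 1.0, size=2)
            f_a = _bias_curve(log2_true[:, a], coeffs, lo, hi,
                              config.bias_amplitude)
            raw[:, a] *= np.exp2(f_a)

    matrix = pd.DataFrame(raw, index=pd.Index(mirnas, name="mirna_id"),
                          columns=arrays)
    sheet = pd.DataFrame({
        "array_id": arrays,
        "patient_id": patient_of,
        "condition": ["scar" if s else "normal" for s in is_scar],
    })
    de_ids = frozenset(mirnas[i] for i in de_idx)
    effects = {mirnas[i]: float(delta[i]) for i in de_idx}
    truth = GroundTruth(de_ids=de_ids, effect_per_id=effects,
                        seed=config.seed)
    return matrix, sheet, truth


def write_dataset(matrix: pd.DataFrame, sheet: pd.DataFrame,
                  truth: GroundTruth, directory: str | Path) -> dict:
    """Write matrix/sheet/truth to ``directory``; returns the file map.

    The files round-trip losslessly through the readers in
    :mod:`mirscar.io`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "raw_matrix.tsv",
        "samples": directory / "sample_sheet.csv",
        "truth": directory / "ground_truth.json",
    }
    io.write_expression_tsv(matrix, paths["matrix"])
    io.write_sample_sheet(sheet, paths["samples"])
    io.write_ground_truth(truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
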