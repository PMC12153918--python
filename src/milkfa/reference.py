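"""Reference parameter set for the Walloon (Belgian) bulk-tank study population.

These tables summarise a large Walloon milk-payment database of FT-MIR
predicted phenotypes: per-trait population standard deviations, per-cluster
trait means for the seven herd-state clusters identified on that population,
the cluster-to-cluster transition probabilities estimated between successive
bulk-tank records, and the cross-validated confusion matrix of the random
forest cluster classifier.  They serve two roles in this package: as the
default generating truth of the synthetic-data module, and as published
benchmark values for the confusion-matrix metrics.

Cluster semantics (Walloon population): clusters 1 and 4 are the common
"healthy" profiles, cluster 7 a de-novo-FA-rich healthy profile, cluster 5
intermediate, clusters 2 and 6 transient stress profiles, and cluster 3 the
abnormal profile consistently associated with degraded herd status.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The 31 fatty-acid traits used throughout (g/100 g fat after conversion).
FA_TRAITS: tuple[str, ...] = (
    "C4", "C6", "C8", "C10", "C12", "C14", "C14:1c9", "C16", "C16:1", "C17",
    "C18", "C18:1t", "C18:1c9", "C18:1c", "C18:2", "C18:2c9c12",
    "C18:2c9t11", "C18:3c9c12c15", "SFA", "MUFA", "PUFA", "UFA", "SCFA",
    "MCFA", "LCFA", "BFA", "omega3", "omega6", "OCFA", "tFA", "C18:1",
)

#: Auxiliary FT-MIR-predicted phenotypes simulated alongside the FAs.
AUX_TRAITS: tuple[str, ...] = (
    "milk_yield", "energy_balance", "nitrogen_efficiency", "blood_bhb",
    "blood_ffa", "dmi",
)

#: Milk composition traits kept on the g/dL-milk basis.
COMPOSITION_TRAITS: tuple[str, ...] = ("fat", "protein")

ALL_TRAITS: tuple[str, ...] = FA_TRAITS + COMPOSITION_TRAITS + AUX_TRAITS

N_CLUSTERS = 7

# Per-cluster means, Walloon population.  Rows: trait; columns: cluster 1..7.
# FA traits in g/100 g fat; fat/protein in g/dL milk; auxiliaries in their
# native prediction units (kg/day, index points, log mmol/L, ueq/L, kg/day).
_CLUSTER_MEAN_ROWS: dict[str, tuple[float, ...]] = {
    "C4": (2.78, 2.87, 2.49, 2.69, 2.55, 2.60, 2.50),
    "C6": (1.82, 1.70, 1.46, 1.86, 1.70, 1.56, 1.84),
    "C8": (1.16, 1.01, 0.88, 1.23, 1.11, 0.94, 1.26),
    "C10": (2.53, 2.06, 1.78, 2.77, 2.51, 1.87, 3.06),
    "C12": (3.15, 2.51, 2.30, 3.51, 3.13, 2.44, 3.78),
    "C14": (11.13, 9.56, 9.05, 12.07, 10.55, 9.92, 11.90),
    "C14:1c9": (1.01, 0.84, 1.00, 1.12, 1.05, 1.05, 1.09),
    "C16": (31.04, 27.16, 24.26, 34.38, 25.78, 30.01, 29.31),
    "C16:1": (1.58, 1.69, 1.95, 1.59, 1.70, 1.92, 1.60),
    "C17": (0.64, 0.66, 0.72, 0.61, 0.70, 0.66, 0.70),
    "C18": (10.02, 11.48, 10.44, 9.04, 9.56, 9.93, 9.18),
    "C18:1t": (3.21, 3.71, 4.44, 2.50, 4.21, 3.13, 3.58),
    "C18:1c9": (19.06, 23.82, 26.28, 16.56, 21.81, 23.26, 17.98),
    "C18:1c": (20.61, 25.69, 28.17, 17.97, 23.39, 25.07, 19.27),
    "C18:2": (2.12, 2.40, 2.42, 1.92, 2.39, 2.08, 2.28),
    "C18:2c9c12": (1.28, 1.47, 1.20, 1.22, 1.20, 1.21, 1.26),
    "C18:2c9t11": (0.46, 0.53, 0.63, 0.38, 0.63, 0.45, 0.57),
    "C18:3c9c12c15": (0.72, 0.80, 1.38, 0.50, 1.33, 0.79, 1.08),
    "SFA": (68.37, 63.15, 57.54, 71.93, 61.53, 64.06, 67.24),
    "MUFA": (27.38, 32.76, 36.15, 24.32, 30.99, 32.12, 26.20),
    "PUFA": (3.46, 4.01, 4.60, 2.86, 4.56, 3.36, 4.19),
    "UFA": (30.91, 36.81, 40.92, 27.29, 35.65, 35.71, 30.40),
    "SCFA": (8.71, 7.92, 6.88, 9.06, 8.24, 7.35, 9.04),
    "MCFA": (50.62, 44.07, 41.79, 55.53, 45.67, 48.20, 51.00),
    "LCFA": (39.84, 47.81, 49.86, 34.80, 43.67, 44.21, 38.00),
    "BFA": (2.21, 2.20, 2.66, 2.11, 2.70, 2.26, 2.54),
    "omega3": (0.59, 0.68, 0.77, 0.47, 0.76, 0.56, 0.70),
    "omega6": (2.17, 2.48, 2.36, 1.95, 2.36, 2.03, 2.34),
    "OCFA": (3.74, 3.73, 4.29, 3.59, 4.34, 3.75, 4.26),
    "tFA": (4.00, 4.58, 5.54, 3.16, 5.32, 3.88, 4.56),
    "C18:1": (23.85, 29.40, 32.28, 20.64, 27.24, 28.27, 22.49),
    "fat": (4.11, 3.94, 4.01, 4.23, 4.10, 4.05, 4.25),
    "protein": (3.44, 3.31, 3.43, 3.50, 3.50, 3.37, 3.55),
    "milk_yield": (26.87, 26.10, 22.45, 28.11, 24.49, 24.81, 25.52),
    "energy_balance": (-2.75, -5.40, -8.50, -1.43, -7.40, -4.83, -4.04),
    "nitrogen_efficiency": (56.67, 56.29, 31.04, 58.10, 38.73, 41.78, 49.67),
    "blood_bhb": (-0.81, -0.74, -0.71, -0.87, -0.73, -0.77, -0.79),
    "blood_ffa": (526.90, 678.60, 714.60, 407.70, 590.40, 629.00, 520.30),
    "dmi": (22.24, 19.93, 19.78, 23.51, 22.03, 20.84, 24.17),
}

# Whole-population standard deviations, Walloon dataset (same units).
_TRAIT_SD: dict[str, float] = {
    "C4": 0.19, "C6": 0.12, "C8": 0.10, "C10": 0.36, "C12": 0.44,
    "C14": 0.87, "C14:1c9": 0.11, "C16": 3.25, "C16:1": 0.17, "C17": 0.05,
    "C18": 1.03, "C18:1t": 0.75, "C18:1c9": 2.63, "C18:1c": 2.78,
    "C18:2": 0.22, "C18:2c9c12": 0.15, "C18:2c9t11": 0.10,
    "C18:3c9c12c15": 0.33, "SFA": 4.09, "MUFA": 3.11, "PUFA": 0.68,
    "UFA": 3.57, "SCFA": 0.60, "MCFA": 3.95, "LCFA": 4.12, "BFA": 0.26,
    "omega3": 0.12, "omega6": 0.24, "OCFA": 0.35, "tFA": 0.93, "C18:1": 3.08,
    "fat": 0.34, "protein": 0.19, "milk_yield": 2.85, "energy_balance": 3.36,
    "nitrogen_efficiency": 14.12, "blood_bhb": 0.09, "blood_ffa": 131.57,
    "dmi": 2.14,
}

# Cluster transition probabilities between successive bulk-tank records
# (Walloon population), in percent; row = cluster at time t, column = t + 1.
_TRANSITIONS_PCT = np.array([
    [65.63, 1.26, 0.09, 20.19, 5.97, 1.69, 5.17],
    [40.24, 32.52, 2.32, 4.97, 10.86, 8.90, 0.20],
    [2.78, 2.85, 55.75, 0.45, 23.67, 14.33, 0.17],
    [22.02, 0.14, 0.01, 69.81, 0.43, 0.53, 7.06],
    [20.68, 1.23, 2.25, 1.62, 64.65, 3.00, 6.56],
    [24.01, 4.21, 6.55, 8.02, 13.18, 43.42, 0.62],
    [19.83, 0.02, 0.01, 27.80, 5.54, 0.12, 46.68],
])

# Published out-of-fold confusion matrix of the random forest classifier on
# the 31 FAs (27,322-record clustering subset); rows = predicted cluster,
# columns = reference cluster.
RF_CONFUSION = np.array([
    [5781, 122, 0, 279, 100, 113, 59],
    [78, 1651, 24, 0, 30, 57, 0],
    [0, 43, 2979, 0, 105, 72, 0],
    [287, 0, 0, 5875, 0, 36, 46],
    [50, 36, 111, 1, 4001, 48, 62],
    [96, 33, 90, 36, 46, 2623, 8],
    [53, 0, 0, 24, 59, 4, 2204],
])

#: Published cross-validated performance of that random forest (percent).
RF_ACCURACY_PCT = 91.81
RF_KAPPA_PCT = 90.14

#: Default alert mapping for the Walloon cluster numbering.
DEFAULT_FLAG_MAP: dict[int, str] = {
    1: "green", 2: "orange", 3: "red", 4: "green",
    5: "orange", 6: "orange", 7: "green",
}

# Whether a high trait value is favourable, per the interpretation of the
# Walloon clusters (editable; ships as a default, never a biological law).
# De novo / short- and medium-chain FAs, saturation and the productivity
# auxiliaries read "high is good"; mobilisation markers read "high is bad".
DEFAULT_TRAIT_ORIENTATION: dict[str, bool] = {
    "C4": True, "C6": True, "C8": True, "C10": True, "C12": True,
    "C14": True, "C14:1c9": True, "C16": True, "C16:1": False, "C17": False,
    "C18": False, "C18:1t": False, "C18:1c9": False, "C18:1c": False,
    "C18:2": False, "C18:2c9c12": False, "C18:2c9t11": False,
    "C18:3c9c12c15": False, "SFA": True, "MUFA": False, "PUFA": False,
    "UFA": False, "SCFA": True, "MCFA": True, "LCFA": False, "BFA": False,
    "omega3": False, "omega6": False, "OCFA": False, "tFA": False,
    "C18:1": False, "fat": True, "protein": True, "milk_yield": True,
    "energy_balance": True, "nitrogen_efficiency": True, "blood_bhb": True,
    "blood_ffa": False, "dmi": True,
}


def cluster_means() -> pd.DataFrame:
    """Per-cluster trait means as a (7 clusters x traits) DataFrame.

    Index is the cluster id 1..7; columns follow :data:`ALL_TRAITS`.
    """
    df = pd.DataFrame(_CLUSTER_MEAN_ROWS, index=pd.RangeIndex(1, 8, name="state_id"))
    return df[list(ALL_TRAITS)]


def trait_sds() -> pd.Series:
    """Whole-population per-trait standard deviations (same trait order)."""
    return pd.Series(_TRAIT_SD, name="sd")[list(ALL_TRAITS)]


def transition_matrix_pct(renormalize: bool = True) -> np.ndarray:
    """Reference 7x7 transition matrix in percent.

    Printed rows carry rounding error of up to 0.01 pp; with
    ``renormalize`` each row is rescaled to sum to exactly 100.
    """
    tm = _TRANSITIONS_PCT.copy()
    if renormalize:
        tm *= 100.0 / tm.sum(axis=1, keepdims=True)
    return tm


def transition_matrix() -> np.ndarray:
    """Reference transition matrix as row-stochastic probabilities."""
    return transition_matrix_pct() / 100.0
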