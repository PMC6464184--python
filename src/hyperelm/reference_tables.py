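"""Bundled published accuracy tables used as worked examples.

Two small CSV tables ship with the package, holding recognition accuracies
reported for multispectral palmprint recognition on the PolyU and CASIA
databases:

* ``activation_runs.csv`` — ten repeated-run accuracies per activation
  function (sigmoid / sin / atan) per database, for comparing activations
  with the two-sample t-test;
* ``method_noise_accuracies.csv`` — per-method accuracies under the pure,
  Gaussian-noise, salt & pepper and speckle conditions on both databases
  (eight values per method), for method-versus-method t-tests.

They serve as fixed worked-example inputs for the significance-test
utilities; the package does not depend on the underlying image databases.
"""

from __future__ import annotations

import csv
from importlib import resources

import numpy as np

__all__ = ["load_activation_runs", "load_method_accuracies"]


def _read_csv(name: str) -> list[dict[str, str]]:
    ref = resources.files("hyperelm.data").joinpath(name)
    with ref.open("r", newline="") as fh:
        return list(csv.DictReader(fh))


def load_activation_runs() -> dict[tuple[str, str], np.ndarray]:
    """Repeated-run accuracies keyed by ``(database, activation)``.

    Databases are ``polyu`` / ``casia``; activations ``sigmoid`` / ``sin`` /
    ``atan``; each value is the array of ten per-run accuracy percentages.
    """
    out: dict[tuple[str, str], list[float]] = {}
    for row in _read_csv("activation_runs.csv"):
        out.setdefault((row["database"], row["activation"]), []).append(
            float(row["accuracy"])
        )
    return {k: np.asarray(v) for k, v in out.items()}


def load_method_accuracies() -> dict[str, np.ndarray]:
    """Per-method accuracies over the eight database x condition cells.

    Methods include the hypercomplex models (``HELM``, ``PCA+HELM``,
    ``LBP+HELM``) and the comparison fusion schemes (``IPCA``, ``MPCA``,
    ``IDWT``, ``MDWT``, ``QPCA``, ``MPELM``, ``TELM``).  Cell order is
    PolyU then CASIA, each pure / gaussian / saltpepper / speckle.
    """
    out: dict[str, list[float]] = {}
    for row in _read_csv("method_noise_accuracies.csv"):
        out.setdefault(row["method"], []).append(float(row["accuracy"]))
    return {k: np.asarray(v) for k, v in out.items()}
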