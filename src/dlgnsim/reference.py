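"""The calibrated reference relay cell ("open-eye" control model).

The shipped parameter file ``data/reference_cell.yaml`` is a versioned
calibration artefact: a single parameter set satisfying, simultaneously,

* resting potential -76 mV with no injected current;
* -69 mV under a +13 pA continuous bias (input resistance ~ 0.54 GOhm);
* a 47-pA / 800-ms step from rest evokes 3 APs at the control Kv1
  conductance (41.7 nS soma / 23 nS axon) and 10 APs with gKv1 = 0;
* low-threshold burst from hyperpolarized holding, tonic firing when
  depolarized.

All in-silico experiments derive their conditions from this cell.  The
47-pA comparison uses the 0-pA (-76 mV) holding regime.
"""

from __future__ import annotations

from importlib import resources

from .cell import CellParameters

__all__ = ["reference_cell", "CONTROL_GKV1"]

#: control Kv1 maximal conductance (nS): (somato-dendritic, axonal)
CONTROL_GKV1 = (41.7, 23.0)

_cache: dict[str, CellParameters] = {}


def reference_cell() -> CellParameters:
    """Load the calibrated reference parameter set."""
    if "ref" not in _cache:
        from .io import load_cell
        with resources.as_file(
            resources.files("dlgnsim").joinpath("data/reference_cell.yaml")
        ) as path:
            _cache["ref"] = load_cell(path)
    return _cache["ref"]
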