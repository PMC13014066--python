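"""Reference pharmacophore inventories for the three iron-chelator
complexes of human 5-lipoxygenase (NDGA, zileuton, BW B70C).

These models transcribe the published per-complex feature
inventories — which feature types each complex contributes and which
active-site residues they engage — onto SYNTHETIC coordinates: the
geometry is an invented but internally consistent pocket layout
(shared features coincide across models to within a fraction of the
match radius; distinct features are well separated), not crystal- or
docking-derived positions. They exist so the consensus-building rules
can be exercised and validated against the published feature
bookkeeping without any external structure files.

Shared by all three complexes: the iron-binding feature (M1), the
donor to Ile673 (D1) and two hydrophobic features (H1 at the pocket
entrance: Leu368/Ala410/Leu414/Ile415/Leu607; H3 in the deeper
cavity: Phe421/Trp599/Ala603). NDGA and BW B70C additionally share a
hydrophobic feature on Phe359/Val604 (H4); zileuton and BW B70C share
a negative-ionizable feature on the N-hydroxyurea warhead (NI1).
NDGA alone contributes donors D2-D5 (His372, Ile673, His367, Asn425)
and acceptors A1-A4 (Arg596 x3, His600); BW B70C alone contributes a
secondary hydrophobic contact H5 (Ala603/Val604).
"""

from __future__ import annotations

import numpy as np

from .perceive import ExcludedVolume, Feature, PharmacophoreModel, label_features

_FE = ("B", 701, "")

# group name -> (ftype, center, provenance residues, members)
_GROUPS: dict[str, tuple] = {
    "M1": ("METAL", (0.0, 0.0, 0.0), [_FE], ("ndga", "zileuton", "bwb70c")),
    "D1": ("HBD", (2.8, 0.0, 0.0), [("B", 673, "")], ("ndga", "zileuton", "bwb70c")),
    "H1": ("HYD", (5.0, 3.0, 0.0),
           [("B", 368, ""), ("B", 410, ""), ("B", 414, ""), ("B", 415, ""), ("B", 607, "")],
           ("ndga", "zileuton", "bwb70c")),
    "H3": ("HYD", (2.0, -3.0, 4.0),
           [("B", 421, ""), ("B", 599, ""), ("B", 603, "")],
           ("ndga", "zileuton", "bwb70c")),
    "H4": ("HYD", (-4.0, 4.0, 3.0), [("B", 359, ""), ("B", 604, "")],
           ("ndga", "bwb70c")),
    "NI1": ("NI", (1.5, 2.5, -2.0), [], ("zileuton", "bwb70c")),
    "D2": ("HBD", (6.0, 2.0, 4.0), [("B", 372, "")], ("ndga",)),
    "D3": ("HBD", (4.0, -1.0, 5.0), [("B", 673, "")], ("ndga",)),
    "D4": ("HBD", (7.0, -2.0, 1.0), [("B", 367, "")], ("ndga",)),
    "D5": ("HBD", (-2.0, 6.0, -3.0), [("B", 425, "")], ("ndga",)),
    "A1": ("HBA", (8.0, 1.0, -2.0), [("B", 596, "")], ("ndga",)),
    "A2": ("HBA", (9.0, 3.5, -1.0), [("B", 596, "")], ("ndga",)),
    "A3": ("HBA", (8.5, 6.0, 0.5), [("B", 596, "")], ("ndga",)),
    "A4": ("HBA", (6.0, 5.0, -4.0), [("B", 600, "")], ("ndga",)),
    "H5": ("HYD", (-5.0, -3.0, 4.0), [("B", 603, ""), ("B", 604, "")],
           ("bwb70c",)),
}

# small per-model offsets so shared features coincide only approximately
_MODEL_OFFSET = {
    "ndga": np.zeros(3),
    "zileuton": np.array([0.20, -0.15, 0.10]),
    "bwb70c": np.array([-0.15, 0.20, -0.20]),
}

_TOL = {"METAL": 1.0, "HBD": 1.5, "HBA": 1.5, "HYD": 1.5, "NI": 1.5}

#: 17 excluded-volume positions common to all three models (a coarse
#: shell around the pocket), pairwise >= 3 A apart
_COMMON_EV = [
    (8.0, 0.0, 0.0), (-8.0, 0.0, 0.0), (0.0, 8.0, 0.0), (0.0, -8.0, 0.0),
    (0.0, 0.0, 8.0), (0.0, 0.0, -8.0), (5.7, 5.7, 0.0), (-5.7, 5.7, 0.0),
    (5.7, -5.7, 0.0), (-5.7, -5.7, 0.0), (5.7, 0.0, 5.7), (-5.7, 0.0, 5.7),
    (0.0, 5.7, 5.7), (0.0, -5.7, 5.7), (5.7, 0.0, -5.7), (0.0, 5.7, -5.7),
    (4.6, 4.6, 4.6),
]

#: volumes present in only one model; far from the common shell so they
#: can never complete a three-way overlap
_UNIQUE_EV = {
    "ndga": [(14.0, 0.0, 0.0), (0.0, 14.0, 0.0)],
    "zileuton": [(-14.0, 0.0, 0.0)],
    "bwb70c": [(0.0, -14.0, 0.0), (0.0, 0.0, 14.0), (14.0, 14.0, 0.0)],
}

_EV_RADIUS = 1.2


def reference_feature_sets() -> dict[str, PharmacophoreModel]:
    """The three per-complex models keyed 'ndga', 'zileuton', 'bwb70c'.

    Coordinates are synthetic (see module docstring); feature types,
    per-model membership and provenance residues follow the published
    inventories, so consensus building on these models reproduces the
    published retention bookkeeping.
    """
    models: dict[str, PharmacophoreModel] = {}
    for mid, offset in _MODEL_OFFSET.items():
        feats = []
        for name, (ftype, center, prov, members) in _GROUPS.items():
            if mid not in members:
                continue
            center = np.asarray(center, float) + offset
            direction = None
            if ftype in ("HBD", "HBA", "METAL"):
                d = -center if np.linalg.norm(center) > 1e-9 else np.array([1.0, 0, 0])
                direction = d / np.linalg.norm(d)
            feats.append(Feature(label=name, ftype=ftype, center=center,
                                 tolerance=_TOL[ftype], direction=direction,
                                 provenance=list(prov)))
        vols = [ExcludedVolume(np.asarray(c, float) + offset, _EV_RADIUS)
                for c in _COMMON_EV + _UNIQUE_EV[mid]]
        models[mid] = label_features(
            PharmacophoreModel(complex_id=mid, features=feats, volumes=vols))
    return models
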