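"""Reading, writing and validation of stoichiometric models and flux tables.

A model is the pair (S, bounds) of a constraint-based metabolic reconstruction
together with a linear biomass functional lambda(v) = xi . v whose value is the
growth rate in 1/h.  Three on-disk dialects are supported:

* ``json`` -- a self-contained dialect (see :func:`write_model_json`) used for
  fixtures and small networks;
* ``tsv`` -- one reaction per row with a compact ``met:coef`` stoichiometry
  column;
* ``sbml`` -- SBML L3 + FBC, read and written through cobrapy; the FBC
  objective is interpreted as the biomass functional.

Reversibility is encoded purely through signed bounds; reactions are never
split into forward/backward pairs.  Formally unbounded fluxes are capped at a
configurable ``default_cap`` so the polytope is bounded.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ModelFormatError

#: default cap (mmol/gDW/h) replacing infinite bounds so the polytope is bounded
DEFAULT_FLUX_CAP = 1.0e4


@dataclass
class StoichiometricModel:
    """A stoichiometric network with flux bounds and a biomass functional.

    Attributes
    ----------
    metabolite_ids : list of str
        Balanced species; their concentrations enter only through the
        steady-state condition S v = 0.
    reaction_ids : list of str
    S : ndarray, shape (M, N)
        Stoichiometric coefficients S[mu, i] of metabolite mu in reaction i.
    lb, ub : ndarray, shape (N,)
        Flux bounds (mmol/gDW/h; the biomass flux itself is in 1/h).
    biomass : ndarray, shape (N,)
        Coefficients xi of the growth functional lambda(v) = xi . v.
    biomass_id : str or None
        Set when the biomass was specified as a single reaction.
    """

    metabolite_ids: list
    reaction_ids: list
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    biomass: np.ndarray
    biomass_id: str | None = None
    name: str = "model"

    def __post_init__(self):
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        if self.S.size == 0:
            self.S = self.S.reshape(0, len(self.reaction_ids))
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        M, N = self.S.shape
        if M != len(self.metabolite_ids):
            raise ModelFormatError(
                f"S has {M} rows but {len(self.metabolite_ids)} metabolite ids")
        for vec, nm in ((self.lb, "lb"), (self.ub, "ub"), (self.biomass, "biomass")):
            if vec.shape != (N,):
                raise ModelFormatError(f"{nm} has length {vec.shape}, expected {N}")
        if np.any(self.lb > self.ub + 1e-12):
            bad = self.reaction_ids[int(np.argmax(self.lb > self.ub))]
            raise ModelFormatError(f"lb > ub for reaction '{bad}'")

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    @property
    def reversible(self) -> np.ndarray:
        """Boolean flags: a reaction is reversible iff its lower bound is negative."""
        return self.lb < 0

    def growth(self, v: np.ndarray) -> np.ndarray:
        """Growth rate lambda(v) = xi . v for one flux vector or a stack of them."""
        return np.asarray(v) @ self.biomass

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id '{rid}'") from None


@dataclass
class MeasuredFluxTable:
    """Measured fluxes V_i, normalized to a reference uptake (dimensionless)."""

    reaction_ids: list
    values: np.ndarray
    sds: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.sds is not None:
            self.sds = np.asarray(self.sds, dtype=float)
        if len(self.reaction_ids) != self.values.size or self.values.size < 1:
            raise ModelFormatError("flux table needs >= 1 row with matching ids/values")

    @property
    def n_fluxes(self) -> int:
        return self.values.size


@dataclass
class ValidationReport:
    zero_rows: list = field(default_factory=list)
    fixed_fluxes: list = field(default_factory=list)
    blocked_reactions: list = field(default_factory=list)
    duplicate_ids: list = field(default_factory=list)
    issues: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_model(model: StoichiometricModel) -> ValidationReport:
    """Report structural oddities (never raises): zero rows, fixed and blocked
    fluxes, duplicate identifiers."""
    rep = ValidationReport()
    for seq, kind in ((model.metabolite_ids, "metabolite"), (model.reaction_ids, "reaction")):
        seen = set()
        for x in seq:
            if x in seen:
                rep.duplicate_ids.append(x)
                rep.issues.append(f"duplicate {kind} id '{x}'")
            seen.add(x)
    if model.n_metabolites:
        dead = np.all(model.S == 0.0, axis=1)
        for mu in np.flatnonzero(dead):
            mid = model.metabolite_ids[mu]
            rep.zero_rows.append(mid)
            rep.issues.append(f"metabolite '{mid}' participates in no reaction")
    fixed = np.isclose(model.lb, model.ub)
    for i in np.flatnonzero(fixed):
        rid = model.reaction_ids[i]
        rep.fixed_fluxes.append(rid)
        if model.lb[i] == 0.0:
            rep.blocked_reactions.append(rid)
    return rep


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _cap(x, default, cap):
    if x is None:
        return default
    x = float(x)
    if math.isinf(x):
        return math.copysign(cap, x)
    return x


def _model_to_dict(model: StoichiometricModel) -> dict:
    reactions = []
    for i, rid in enumerate(model.reaction_ids):
        stoich = {model.metabolite_ids[mu]: float(model.S[mu, i])
                  for mu in np.flatnonzero(model.S[:, i] != 0.0)}
        reactions.append({"id": rid, "stoich": stoich,
                          "lb": float(model.lb[i]), "ub": float(model.ub[i])})
    if model.biomass_id is not None:
        biomass = model.biomass_id
    else:
        biomass = {rid: float(c) for rid, c in zip(model.reaction_ids, model.biomass)
                   if c != 0.0}
    return {"name": model.name, "metabolites": list(model.metabolite_ids),
            "reactions": reactions, "biomass": biomass}


def _model_from_dict(doc: dict, cap: float) -> StoichiometricModel:
    try:
        met_ids = list(doc["metabolites"])
        rxns = doc["reactions"]
        biomass_spec = doc["biomass"]
    except KeyError as e:
        raise ModelFormatError(f"model document missing key {e}") from None
    rid_list = [r["id"] for r in rxns]
    met_index = {m: k for k, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rid_list)))
    lb = np.empty(len(rid_list))
    ub = np.empty(len(rid_list))
    for i, r in enumerate(rxns):
        for m, c in r.get("stoich", {}).items():
            if m not in met_index:
                raise ModelFormatError(
                    f"reaction '{r['id']}' references unknown metabolite '{m}'")
            S[met_index[m], i] = float(c)
        lb[i] = _cap(r.get("lb"), -cap, cap)
        ub[i] = _cap(r.get("ub"), cap, cap)
    biomass_id = None
    if isinstance(biomass_spec, str):
        biomass_id = biomass_spec
        if biomass_spec not in rid_list:
            raise ModelFormatError(f"biomass reaction '{biomass_spec}' not in model")
        xi = np.zeros(len(rid_list))
        xi[rid_list.index(biomass_spec)] = 1.0
    elif isinstance(biomass_spec, dict):
        xi = np.zeros(len(rid_list))
        for rid, c in biomass_spec.items():
            if rid not in rid_list:
                raise ModelFormatError(f"biomass coefficient for unknown reaction '{rid}'")
            xi[rid_list.index(rid)] = float(c)
    else:
        raise ModelFormatError("biomass must be a reaction id or a coefficient map")
    return StoichiometricModel(met_ids, rid_list, S, lb, ub, xi,
                               biomass_id=biomass_id, name=doc.get("name", "model"))


def write_model_json(model: StoichiometricModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh, indent=1)


# ---------------------------------------------------------------------------
# TSV dialect: reaction_id <tab> stoichiometry <tab> lb <tab> ub <tab> biomass
# stoichiometry is space-separated "met:coef" terms ('.' for none).
# ---------------------------------------------------------------------------

def write_model_tsv(model: StoichiometricModel, path) -> None:
    rows = []
    for i, rid in enumerate(model.reaction_ids):
        terms = [f"{model.metabolite_ids[mu]}:{model.S[mu, i]:.17g}"
                 for mu in np.flatnonzero(model.S[:, i] != 0.0)]
        rows.append((rid, " ".join(terms) or ".", repr(float(model.lb[i])),
                     repr(float(model.ub[i])), repr(float(model.biomass[i]))))
    df = pd.DataFrame(rows, columns=["reaction_id", "stoichiometry", "lb", "ub", "biomass"])
    df.to_csv(path, sep="\t", index=False)


def _load_model_tsv(path, cap: float) -> StoichiometricModel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"reaction_id", "stoichiometry", "lb", "ub", "biomass"}
    if not need.issubset(df.columns):
        raise ModelFormatError(f"model TSV needs columns {sorted(need)}")
    met_ids, met_index = [], {}
    rid_list = list(df["reaction_id"])
    stoichs = []
    for rid, s in zip(rid_list, df["stoichiometry"]):
        terms = {}
        if s.strip() != ".":
            for term in s.split():
                try:
                    m, c = term.rsplit(":", 1)
                    terms[m] = float(c)
                except ValueError:
                    raise ModelFormatError(
                        f"bad stoichiometry term '{term}' in reaction '{rid}'") from None
                if m not in met_index:
                    met_index[m] = len(met_ids)
                    met_ids.append(m)
        stoichs.append(terms)
    S = np.zeros((len(met_ids), len(rid_list)))
    for i, terms in enumerate(stoichs):
        for m, c in terms.items():
            S[met_index[m], i] = c
    lb = np.array([_cap(float(x), -cap, cap) for x in df["lb"]])
    ub = np.array([_cap(float(x), cap, cap) for x in df["ub"]])
    xi = df["biomass"].astype(float).to_numpy()
    return StoichiometricModel(met_ids, rid_list, S, lb, ub, xi)


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------

def _load_model_sbml(path, cap: float) -> StoichiometricModel:
    import cobra
    from cobra.util.array import create_stoichiometric_matrix

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as e:  # cobra raises a zoo of exceptions
        raise ModelFormatError(f"could not parse SBML '{path}': {e}") from e
    S = create_stoichiometric_matrix(cm)
    met_ids = [m.id for m in cm.metabolites]
    rid_list = [r.id for r in cm.reactions]
    lb = np.array([_cap(r.lower_bound, -cap, cap) for r in cm.reactions])
    ub = np.array([_cap(r.upper_bound, cap, cap) for r in cm.reactions])
    xi = np.array([r.objective_coefficient for r in cm.reactions], dtype=float)
    if not np.any(xi):
        raise ModelFormatError(f"SBML model '{path}' declares no FBC objective "
                               "(needed as the biomass functional)")
    nz = np.flatnonzero(xi)
    biomass_id = rid_list[nz[0]] if (nz.size == 1 and xi[nz[0]] == 1.0) else None
    return StoichiometricModel(met_ids, rid_list, S, lb, ub, xi,
                               biomass_id=biomass_id, name=cm.id or "model")


def write_model_sbml(model: StoichiometricModel, path) -> None:
    import cobra

    cm = cobra.Model(model.name)
    mets = [cobra.Metabolite(mid, compartment="c") for mid in model.metabolite_ids]
    cm.add_metabolites(mets)
    rxns = []
    for i, rid in enumerate(model.reaction_ids):
        rx = cobra.Reaction(rid)
        rx.lower_bound = float(model.lb[i])
        rx.upper_bound = float(model.ub[i])
        rxns.append(rx)
    cm.add_reactions(rxns)
    for i, rx in enumerate(rxns):
        rx.add_metabolites({mets[mu]: float(model.S[mu, i])
                            for mu in np.flatnonzero(model.S[:, i] != 0.0)})
    cm.objective = {rx: float(c) for rx, c in zip(rxns, model.biomass) if c != 0.0}
    cobra.io.write_sbml_model(cm, str(path))


# ---------------------------------------------------------------------------

_LOADERS = {"json": None, "tsv": _load_model_tsv, "sbml": _load_model_sbml}


def load_model(path, format: str = "json", *, cap: float = DEFAULT_FLUX_CAP,
               validate: bool = True) -> StoichiometricModel:
    """Load a stoichiometric model from ``path`` in the named ``format``.

    Infinite or missing bounds are replaced by ``+-cap``.  With ``validate``
    (default) a model failing structural validation raises
    :class:`ModelFormatError` listing the issues.
    """
    if format == "json":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ModelFormatError(f"could not parse JSON '{path}': {e}") from e
        model = _model_from_dict(doc, cap)
    elif format in _LOADERS and _LOADERS[format]:
        model = _LOADERS[format](path, cap)
    else:
        raise ModelFormatError(f"unknown model format '{format}'")
    if validate:
        rep = validate_model(model)
        hard = [m for m in rep.issues if "duplicate" in m]
        if hard:
            raise ModelFormatError("; ".join(hard))
    return model


def write_model(model: StoichiometricModel, path, format: str = "json") -> None:
    writer = {"json": write_model_json, "tsv": write_model_tsv,
              "sbml": write_model_sbml}.get(format)
    if writer is None:
        raise ModelFormatError(f"unknown model format '{format}'")
    writer(model, path)


def load_flux_table(path, model: StoichiometricModel | None = None) -> MeasuredFluxTable:
    """Load a TSV of measured relative fluxes (columns ``reaction_id``,
    ``value`` and optionally ``sd``); ids are checked against ``model``."""
    df = pd.read_csv(path, sep="\t")
    if not {"reaction_id", "value"}.issubset(df.columns):
        raise ModelFormatError("flux table needs columns reaction_id, value")
    table = MeasuredFluxTable(list(df["reaction_id"]), df["value"].to_numpy(),
                              df["sd"].to_numpy() if "sd" in df.columns else None)
    if model is not None:
        unknown = [r for r in table.reaction_ids if r not in model.reaction_ids]
        if unknown:
            raise ModelFormatError(f"flux table ids not in model: {unknown}")
    return table
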