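"""Delimited-table readers/writers, posterior archives and SBML export.

All dataset files are tab-separated tables with headers.  Readers validate
the schema strictly and report offending line numbers; every writer
produces files its paired reader accepts unchanged.
"""

from __future__ import annotations

import json
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .model import (
    GeneSpec,
    ModelSpec,
    ParameterVector,
    compile_rates,
    pack_log10,
    param_names,
)
from .likelihood import (
    SS_COLUMNS,
    TC_COLUMNS,
    DataError,
    SteadyStateDataset,
    TimeCourseDataset,
)
from .sampler import SamplerOutput
from .simulate import TrajectorySet
from .validation import VR_COLUMNS, ValidationRates

__all__ = [
    "read_time_course", "write_time_course",
    "read_steady_state", "write_steady_state",
    "read_validation_rates", "write_validation_rates",
    "read_truth", "write_truth",
    "write_trajectory", "read_trajectory",
    "write_draws", "read_draws",
    "write_model_config", "read_model_config",
    "export_sbml", "read_sbml_model",
]

SEP = "\t"


def _read_table(path, columns, numeric) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    df = pd.read_csv(path, sep=SEP, dtype=str, comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header line, one for 1-based numbering
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise DataError(f"{path}: non-numeric {col!r} at line(s) {lines}")
        if parsed.isna().any():
            i = int(df.index[parsed.isna()][0])
            raise DataError(f"{path}: empty {col!r} at line {i + 2}")
        df[col] = parsed
    return df


# -- time course -------------------------------------------------------------

def write_time_course(data: TimeCourseDataset, path) -> None:
    df = data.records.copy()
    df["native_period_min"] = df["experiment"].map(data.native_periods)
    df.to_csv(path, sep=SEP, index=False)


def read_time_course(path) -> TimeCourseDataset:
    df = _read_table(path, TC_COLUMNS + ("native_period_min",),
                     ("time_min", "log_ratio", "native_period_min"))
    periods = df.groupby("experiment")["native_period_min"].agg(["min", "max"])
    if (periods["min"] != periods["max"]).any():
        bad = periods.index[periods["min"] != periods["max"]].tolist()
        raise DataError(f"{path}: inconsistent native_period_min within experiment(s) {bad}")
    native = periods["min"].to_dict()
    return TimeCourseDataset(df[list(TC_COLUMNS)].copy(), native)


# -- steady state ------------------------------------------------------------

def write_steady_state(data: SteadyStateDataset, path) -> None:
    data.records.to_csv(path, sep=SEP, index=False)


def read_steady_state(path) -> SteadyStateDataset:
    df = _read_table(path, SS_COLUMNS, ("log10_conc_uM",))
    return SteadyStateDataset(df[list(SS_COLUMNS)].copy())


# -- validation rates --------------------------------------------------------

def write_validation_rates(rates: ValidationRates, path) -> None:
    rates.records.to_csv(path, sep=SEP, index=False)


def read_validation_rates(path) -> ValidationRates:
    df = _read_table(path, VR_COLUMNS, ("value",))
    return ValidationRates(df[list(VR_COLUMNS)].copy())


# -- truth file --------------------------------------------------------------

def write_truth(pv: ParameterVector, path) -> None:
    """Parameter table on sampling scale (log10 except Hill exponents)."""
    pd.DataFrame({"parameter": pv.names, "value": pv.values}).to_csv(
        path, sep=SEP, index=False
    )


def read_truth(path) -> ParameterVector:
    df = _read_table(path, ("parameter", "value"), ("value",))
    return ParameterVector(tuple(df["parameter"]), df["value"].to_numpy(dtype=float))


# -- trajectories ------------------------------------------------------------

def write_trajectory(traj: TrajectorySet, path) -> None:
    """Tidy table (time_s, species, conc_uM)."""
    n = traj.t.size
    df = pd.DataFrame({
        "time_s": np.tile(traj.t, len(traj.species)),
        "species": np.repeat(traj.species, n),
        "conc_uM": traj.y.ravel(),
    })
    df.to_csv(path, sep=SEP, index=False)


def read_trajectory(path) -> TrajectorySet:
    df = _read_table(path, ("time_s", "species", "conc_uM"), ("time_s", "conc_uM"))
    species = tuple(pd.unique(df["species"]))
    t = df[df["species"] == species[0]]["time_s"].to_numpy(dtype=float)
    y = np.vstack([
        df[df["species"] == s]["conc_uM"].to_numpy(dtype=float) for s in species
    ])
    return TrajectorySet(t=t, y=y, species=species, period=float(t[-1]) / 2.0)


# -- model configuration -----------------------------------------------------

def write_model_config(model: ModelSpec, prior, path) -> None:
    """Declarative model file: variant, period, genes, edges, prior bounds.

    YAML; round-trips losslessly through :func:`read_model_config`.
    """
    import yaml

    doc = {
        "variant": model.variant,
        "period_s": model.period,
        "genes": [
            {k: v for k, v in (
                ("name", g.name),
                ("activator", g.activator),
                ("transcription_inhibitor", g.transcription_inhibitor),
                ("degradation_inhibitor", g.degradation_inhibitor),
            ) if v is not None}
            for g in model.genes
        ],
        "prior": {
            n: [float(lo), float(hi)]
            for n, lo, hi in zip(prior.names, prior.lower, prior.upper)
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_model_config(path):
    """Inverse of :func:`write_model_config`: (ModelSpec, PriorSpec)."""
    import yaml

    from .model import PriorSpec

    doc = yaml.safe_load(Path(path).read_text())
    model = ModelSpec(
        variant=int(doc["variant"]),
        genes=tuple(
            GeneSpec(
                g["name"],
                activator=g.get("activator"),
                transcription_inhibitor=g.get("transcription_inhibitor"),
                degradation_inhibitor=g.get("degradation_inhibitor"),
            )
            for g in doc["genes"]
        ),
        period=float(doc.get("period_s", 4800.0)),
    )
    names = tuple(doc["prior"].keys())
    lo = np.array([doc["prior"][n][0] for n in names])
    hi = np.array([doc["prior"][n][1] for n in names])
    return model, PriorSpec(names, lo, hi)


# -- posterior archive -------------------------------------------------------

def write_draws(output: SamplerOutput, outdir) -> tuple[Path, Path]:
    """Posterior draws as a delimited table plus a JSON run-metadata file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    draws_path = outdir / "draws.tsv"
    meta_path = outdir / "run_meta.json"
    df = pd.DataFrame(output.draws, columns=list(output.names))
    df.insert(0, "log_lik", output.log_lik)
    df.insert(0, "log_prior", output.log_prior)
    df.to_csv(draws_path, sep=SEP, index=False)
    counts_per_replica, total = _round_trip_summary(output)
    meta = {
        "seed": output.seed,
        "settings": output.settings,
        "betas": output.betas.tolist(),
        "swap_rate": output.swap_rate,
        "swap_attempts": output.swap_attempts,
        "final_acceptance": np.asarray(output.acceptance).tolist(),
        "round_trips_total": total,
        "round_trips_per_replica": counts_per_replica,
        "n_draws": int(output.draws.shape[0]),
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return draws_path, meta_path


def _round_trip_summary(output: SamplerOutput):
    from .sampler import count_round_trips

    counts, total = count_round_trips(output.ledger)
    return counts.tolist(), total


def read_draws(outdir) -> tuple[pd.DataFrame, dict]:
    outdir = Path(outdir)
    df = pd.read_csv(outdir / "draws.tsv", sep=SEP)
    meta = json.loads((outdir / "run_meta.json").read_text())
    return df, meta


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANN_NS = "urn:cyclebayes:edges"


def _math(expr) -> ET.Element:
    """Build content MathML from a nested tuple expression.

    ``("times", a, b)`` applies an operator; strings are ``<ci>``
    references and numbers ``<cn>`` constants.
    """
    m = ET.Element(f"{{{MATHML_NS}}}math")
    m.append(_math_node(expr))
    return m


def _math_node(expr) -> ET.Element:
    if isinstance(expr, str):
        ci = ET.Element(f"{{{MATHML_NS}}}ci")
        ci.text = f" {expr} "
        return ci
    if isinstance(expr, (int, float)):
        cn = ET.Element(f"{{{MATHML_NS}}}cn")
        cn.text = f" {expr} "
        return cn
    op, *args = expr
    ap = ET.Element(f"{{{MATHML_NS}}}apply")
    ap.append(ET.Element(f"{{{MATHML_NS}}}{op}"))
    for a in args:
        ap.append(_math_node(a))
    return ap


def _hill_factor(species: str, K: str, h: str):
    return ("divide", 1.0, ("plus", 1.0, ("power", ("divide", species, K), h)))


def export_sbml(model: ModelSpec, params: ParameterVector, path) -> None:
    """Write the model as SBML Level 3 core.

    One compartment, 2 x n_genes species in micromolar, and four reactions
    per gene (transcription, transcript degradation, translation, protein
    degradation) whose kinetic laws reproduce the model rate equations
    term by term.  Regulatory edges are recorded in a small annotation so
    the document round-trips through :func:`read_sbml_model`.
    """
    lin = params.to_linear()
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    mdl = ET.SubElement(root, f"{{{SBML_NS}}}model",
                        {"id": f"cyclin_variant_{model.variant}",
                         "substanceUnits": "mole", "timeUnits": "second"})
    comps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                  {"id": "cell", "size": "1", "spatialDimensions": "3",
                   "constant": "true"})
    sp_list = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    c = compile_rates(model, params)
    init = dict(zip(model.species, np.concatenate([c.m0, c.p0])))
    for s in model.species:
        ET.SubElement(sp_list, f"{{{SBML_NS}}}species", {
            "id": s, "compartment": "cell",
            "initialConcentration": repr(float(init[s])),
            "hasOnlySubstanceUnits": "false", "boundaryCondition": "false",
            "constant": "false",
        })
    par_list = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    for name in params.names:
        ET.SubElement(par_list, f"{{{SBML_NS}}}parameter", {
            "id": name, "value": repr(float(lin[name])), "constant": "true",
        })
    rx_list = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")

    def reaction(rid, reactants, products, modifiers, math_expr, ann=None):
        rx = ET.SubElement(rx_list, f"{{{SBML_NS}}}reaction",
                           {"id": rid, "reversible": "false"})
        if ann:
            annotation = ET.SubElement(rx, f"{{{SBML_NS}}}annotation")
            ET.SubElement(annotation, f"{{{ANN_NS}}}edges", ann)
        if reactants:
            lo = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for s in reactants:
                ET.SubElement(lo, f"{{{SBML_NS}}}speciesReference",
                              {"species": s, "stoichiometry": "1", "constant": "true"})
        if products:
            lo = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for s in products:
                ET.SubElement(lo, f"{{{SBML_NS}}}speciesReference",
                              {"species": s, "stoichiometry": "1", "constant": "true"})
        if modifiers:
            lo = ET.SubElement(rx, f"{{{SBML_NS}}}listOfModifiers")
            for s in modifiers:
                ET.SubElement(lo, f"{{{SBML_NS}}}modifierSpeciesReference",
                              {"species": s})
        kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_math(math_expr))

    for g in model.genes:
        mrna, prot = f"mRNA_{g.name}", f"protein_{g.name}"
        mods = []
        expr = f"beta_{g.name}"
        ann = {}
        if g.activator is not None:
            mods.append(f"protein_{g.activator}")
            ann["activator"] = g.activator
            expr = ("plus", expr, ("times", f"alpha_{g.name}", f"protein_{g.activator}"))
        if g.transcription_inhibitor is not None:
            mods.append(f"protein_{g.transcription_inhibitor}")
            ann["transcription_inhibitor"] = g.transcription_inhibitor
            expr = ("times", expr,
                    _hill_factor(f"protein_{g.transcription_inhibitor}",
                                 f"K_{g.name}", f"h_{g.name}"))
        reaction(f"transcription_{g.name}", [], [mrna], mods, expr, ann or None)
        reaction(f"degradation_mRNA_{g.name}", [mrna], [], [],
                 ("times", "deltam", mrna))
        reaction(f"translation_{g.name}", [], [prot], [mrna],
                 ("times", "kappa", mrna))
        deg_expr = ("times", f"deltap_{g.name}", prot)
        deg_mods, deg_ann = [], None
        if g.degradation_inhibitor is not None:
            deg_mods = [f"protein_{g.degradation_inhibitor}"]
            deg_ann = {"degradation_inhibitor": g.degradation_inhibitor}
            deg_expr = ("times", deg_expr,
                        _hill_factor(f"protein_{g.degradation_inhibitor}",
                                     f"Kdeg_{g.name}", f"hdeg_{g.name}"))
        reaction(f"degradation_protein_{g.name}", [prot], [], deg_mods,
                 deg_expr, deg_ann)

    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_sbml_model(path) -> tuple[ModelSpec, ParameterVector]:
    """Re-import a document written by :func:`export_sbml`."""
    tree = ET.parse(path)
    mdl = tree.getroot().find(f"{{{SBML_NS}}}model")
    if mdl is None:
        raise DataError(f"{path}: not an SBML document")
    mid = mdl.get("id", "")
    try:
        variant = int(mid.rsplit("_", 1)[1])
    except (IndexError, ValueError):
        raise DataError(f"{path}: unrecognized model id {mid!r}")
    genes = []
    for sp in mdl.iter(f"{{{SBML_NS}}}species"):
        sid = sp.get("id", "")
        if sid.startswith("mRNA_"):
            genes.append(sid[len("mRNA_"):])
    edges: dict[str, dict[str, str]] = {g: {} for g in genes}
    for rx in mdl.iter(f"{{{SBML_NS}}}reaction"):
        rid = rx.get("id", "")
        for kind in ("transcription_", "degradation_protein_"):
            if rid.startswith(kind):
                g = rid[len(kind):]
                ann = rx.find(f"{{{SBML_NS}}}annotation/{{{ANN_NS}}}edges")
                if ann is not None:
                    edges[g].update(ann.attrib)
    spec = ModelSpec(
        variant=variant,
        genes=tuple(
            GeneSpec(
                g,
                activator=edges[g].get("activator"),
                transcription_inhibitor=edges[g].get("transcription_inhibitor"),
                degradation_inhibitor=edges[g].get("degradation_inhibitor"),
            )
            for g in genes
        ),
    )
    lin = {
        p.get("id"): float(p.get("value"))
        for p in mdl.iter(f"{{{SBML_NS}}}parameter")
    }
    pv = pack_log10(lin, param_names(spec))
    return spec, pv
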