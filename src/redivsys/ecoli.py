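"""Coarse-grained single-cell *E. coli* growth model.

The model partitions the proteome into four sectors -- transporters (t),
catabolic enzymes (e), ribosomes (r) and housekeeping proteins (q) -- each
with its own mRNA ``m_y`` and ribosome-mRNA complex ``c_y``, plus an
internalised nutrient ``s_int`` and a lumped resource ``a`` (energy
carriers / charged tRNAs).  Reactions: resource-gated transcription
(autorepressed for q), first-order mRNA degradation, reversible ribosome
binding, translation consuming ``n_y`` resource units per protein of length
``n_y``, nutrient import by transporters and catabolism converting each
internal nutrient into ``n_s`` resource units.  Mass is carried by proteins
and ribosome complexes only, so the emergent growth rate is the translation
elongation rate times the concentration of translating ribosomes.

Variants: an operon model where t and e proteins are co-expressed from one
bicistronic mRNA, and a chloramphenicol extension where the drug converts
translating complexes into inactive, dilution-only species ``z_y``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np

from .core import ConfigurationError, RateLaw, ReactionNetwork

__all__ = [
    "SECTORS",
    "ParameterSet",
    "load_default_parameters",
    "build_full_model",
    "build_operon_model",
    "apply_chloramphenicol",
    "build_model",
]

SECTORS = ("t", "e", "r", "q")

_DEFAULT_FIXTURE = "ecoli_default_synthetic.json"


@dataclass
class ParameterSet:
    """Parameters of the coarse-grained cell model.

    Units: time in minutes, mass in amino acids (aa), concentrations per
    unit mass (aa^-1).  Transcription capacities ``w_y`` are per unit mass
    per minute; ``gamma_max`` is the maximal elongation rate in aa per
    minute per ribosome; ``n_s`` is the nutrient quality (resource units
    per imported nutrient molecule) and the dial for growth conditions;
    ``O_c`` is the origin concentration triggering replication initiation
    and ``tau_CD`` the C+D period between initiation and division.
    """

    w: dict = field(default_factory=dict)        # per sector: transcription capacity
    theta: dict = field(default_factory=dict)    # per sector: transcription threshold
    d: dict = field(default_factory=dict)        # per sector: mRNA degradation rate
    n: dict = field(default_factory=dict)        # per sector: protein length (aa)
    K_q: float = 2.2e-3                          # q autorepression threshold
    h: float = 4.0                               # q autorepression Hill exponent
    k_b: float = 2.2e7                           # ribosome-mRNA binding
    k_u: float = 1.0                             # unbinding
    gamma_max: float = 1260.0                    # max elongation rate (aa/min/ribosome)
    K_gamma: float = 3e-5                        # resource threshold for translation
    v_t: float = 726.0                           # import turnover (per min)
    v_m: float = 5800.0                          # catabolic turnover (per min)
    K_m: float = 3e-4                            # catabolism Michaelis constant
    n_s: float = 5.0                             # nutrient quality (resources/nutrient)
    s: float = 1.0                               # external nutrient level (held constant)
    O_c: float = 2e-9                            # origin concentration at initiation
    tau_CD: float = 60.0                         # C+D period (min)
    k_cm: float = 0.003                          # chloramphenicol binding (per min per dose unit)
    X_cm: float = 0.0                            # imposed drug concentration

    def __post_init__(self) -> None:
        for name in ("w", "theta", "d", "n"):
            dd = getattr(self, name)
            missing = [y for y in SECTORS if y not in dd]
            if missing:
                raise ConfigurationError(f"parameter {name!r} missing sectors {missing}")
            if any(v < 0 for v in dd.values()):
                raise ConfigurationError(f"negative entries in {name!r}")
        for y in SECTORS:
            ny = self.n[y]
            if ny <= 0 or int(ny) != ny:
                raise ConfigurationError(f"protein length n_{y} must be a positive integer")
        if self.h < 1:
            raise ConfigurationError("Hill exponent h must be >= 1")
        if self.tau_CD <= 0 and self.tau_CD != 0.0:
            raise ConfigurationError("tau_CD must be >= 0")
        if self.O_c <= 0:
            raise ConfigurationError("O_c must be positive")
        for name in ("k_b", "k_u", "gamma_max", "K_gamma", "v_t", "v_m", "K_m",
                     "n_s", "s", "K_q", "k_cm", "X_cm"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"parameter {name!r} must be non-negative")

    # -- flat parameter view (used by sensitivity analysis / inference) --

    def flatten(self) -> dict:
        flat = {}
        for name in ("w", "theta", "d"):
            for y in SECTORS:
                flat[f"{name}_{y}"] = getattr(self, name)[y]
        for name in ("K_q", "k_b", "k_u", "gamma_max", "K_gamma", "v_t", "v_m",
                     "K_m", "n_s", "O_c", "tau_CD", "k_cm"):
            flat[name] = getattr(self, name)
        return flat

    def replace(self, **flat) -> "ParameterSet":
        """Return a copy with flat-named parameters (``w_t``, ``K_gamma``, ...) replaced."""
        d = asdict(self)
        for key, val in flat.items():
            if key in d:
                d[key] = val
            elif "_" in key and key.rsplit("_", 1)[0] in ("w", "theta", "d", "n") \
                    and key.rsplit("_", 1)[1] in SECTORS:
                base, y = key.rsplit("_", 1)
                d[base] = dict(d[base])
                d[base][y] = val
            else:
                raise ConfigurationError(f"unknown parameter {key!r}")
        return ParameterSet(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_default_parameters() -> ParameterSet:
    """Default *E. coli* parameter set (packaged synthetic fixture).

    The fixture is a synthetic reconstruction: literature-anchored rate
    constants with transcription parameters calibrated so that the model
    reproduces the reported single-cell observables (see docs/methods.md).
    """
    ref = resources.files("redivsys").joinpath(f"data/{_DEFAULT_FIXTURE}")
    return ParameterSet.from_dict(json.loads(ref.read_text()))


def default_fixture_checksum() -> str:
    ref = resources.files("redivsys").joinpath(f"data/{_DEFAULT_FIXTURE}")
    return hashlib.sha256(ref.read_bytes()).hexdigest()


# -- model builders ---------------------------------------------------


def _transcription_law(p: ParameterSet, y: str) -> RateLaw:
    if y == "q":
        return RateLaw(
            "hill_activation_repressed",
            {"w": p.w["q"], "theta": p.theta["q"], "K": p.K_q, "h": p.h},
            {"a": "a", "p": "p_q"},
        )
    return RateLaw("hill_activation", {"w": p.w[y], "theta": p.theta[y]}, {"a": "a"})


def _translation_law(p: ParameterSet, c_name: str, n_y: float) -> RateLaw:
    return RateLaw(
        "translation",
        {"gamma_max": p.gamma_max, "n": n_y, "K": p.K_gamma},
        {"c": c_name, "a": "a"},
    )


def build_full_model(p: ParameterSet) -> ReactionNetwork:
    """Full four-sector model: 14 species, 22 reactions."""
    species = (
        [f"m_{y}" for y in SECTORS]
        + [f"c_{y}" for y in SECTORS]
        + [f"p_{y}" for y in SECTORS]
        + ["s_int", "a"]
    )
    mass = {f"m_{y}": 0.0 for y in SECTORS}
    mass.update({f"c_{y}": float(p.n["r"]) for y in SECTORS})
    mass.update({f"p_{y}": float(p.n[y]) for y in SECTORS})
    mass.update({"s_int": 0.0, "a": 0.0})

    idx = {name: i for i, name in enumerate(species)}
    reactions = []  # (label, group, stoich dict, RateLaw)

    for y in SECTORS:
        reactions.append((f"transcription_{y}", f"transcription:{y}",
                          {f"m_{y}": +1}, _transcription_law(p, y)))
    for y in SECTORS:
        reactions.append((f"degradation_{y}", f"degradation:{y}",
                          {f"m_{y}": -1},
                          RateLaw("linear", {"k": p.d[y]}, {"s": f"m_{y}"})))
    for y in SECTORS:
        reactions.append((f"binding_{y}", f"binding/unbinding:{y}",
                          {"p_r": -1, f"m_{y}": -1, f"c_{y}": +1},
                          RateLaw("mass_action", {"k": p.k_b}, {"s1": "p_r", "s2": f"m_{y}"})))
    for y in SECTORS:
        reactions.append((f"unbinding_{y}", f"binding/unbinding:{y}",
                          {f"c_{y}": -1, "p_r": +1, f"m_{y}": +1},
                          RateLaw("linear", {"k": p.k_u}, {"s": f"c_{y}"})))
    for y in SECTORS:
        # n_y a + c_y -> p_r + m_y + p_y  (for y = r the products are two ribosomes)
        stoich = {"a": -float(p.n[y]), f"c_{y}": -1, f"m_{y}": +1, "p_r": +1}
        stoich[f"p_{y}"] = stoich.get(f"p_{y}", 0) + 1
        reactions.append((f"translation_{y}", f"translation:{y}", stoich,
                          _translation_law(p, f"c_{y}", p.n[y])))
    reactions.append(("import", "import", {"s_int": +1},
                      RateLaw("linear", {"k": p.v_t * p.s}, {"s": "p_t"})))
    reactions.append(("catabolism", "catabolism",
                      {"s_int": -1, "a": +float(p.n_s)},
                      RateLaw("michaelis", {"v": p.v_m, "K": p.K_m},
                              {"e": "p_e", "s": "s_int"})))

    return _assemble(species, mass, idx, reactions, params=p)


def build_operon_model(p: ParameterSet) -> ReactionNetwork:
    """Operon variant: t and e co-expressed from one bicistronic mRNA.

    The t/e-specific reactions are replaced by transcription, degradation,
    binding/unbinding of ``m_bi`` and a single translation event producing
    both proteins: 12 species, 17 reactions.  Each operon translation adds
    mass ``n_t + n_e`` while consuming ``n_e`` resource units, exactly as
    the reaction scheme is written.
    """
    species = (
        ["m_bi", "m_r", "m_q", "c_bi", "c_r", "c_q"]
        + [f"p_{y}" for y in SECTORS]
        + ["s_int", "a"]
    )
    mass = {"m_bi": 0.0, "m_r": 0.0, "m_q": 0.0,
            "c_bi": float(p.n["r"]), "c_r": float(p.n["r"]), "c_q": float(p.n["r"]),
            "s_int": 0.0, "a": 0.0}
    mass.update({f"p_{y}": float(p.n[y]) for y in SECTORS})
    idx = {name: i for i, name in enumerate(species)}

    reactions = []
    reactions.append(("transcription_bi", "transcription:bi", {"m_bi": +1},
                      RateLaw("hill_activation",
                              {"w": p.w["e"], "theta": p.theta["e"]}, {"a": "a"})))
    for y in ("r", "q"):
        reactions.append((f"transcription_{y}", f"transcription:{y}",
                          {f"m_{y}": +1}, _transcription_law(p, y)))
    reactions.append(("degradation_bi", "degradation:bi", {"m_bi": -1},
                      RateLaw("linear", {"k": p.d["e"]}, {"s": "m_bi"})))
    for y in ("r", "q"):
        reactions.append((f"degradation_{y}", f"degradation:{y}", {f"m_{y}": -1},
                          RateLaw("linear", {"k": p.d[y]}, {"s": f"m_{y}"})))
    for tag in ("bi", "r", "q"):
        reactions.append((f"binding_{tag}", f"binding/unbinding:{tag}",
                          {"p_r": -1, f"m_{tag}": -1, f"c_{tag}": +1},
                          RateLaw("mass_action", {"k": p.k_b}, {"s1": "p_r", "s2": f"m_{tag}"})))
    for tag in ("bi", "r", "q"):
        reactions.append((f"unbinding_{tag}", f"binding/unbinding:{tag}",
                          {f"c_{tag}": -1, "p_r": +1, f"m_{tag}": +1},
                          RateLaw("linear", {"k": p.k_u}, {"s": f"c_{tag}"})))
    # n_e a + c_bi -> m_bi + p_r + p_t + p_e
    reactions.append(("translation_bi", "translation:bi",
                      {"a": -float(p.n["e"]), "c_bi": -1, "m_bi": +1,
                       "p_r": +1, "p_t": +1, "p_e": +1},
                      _translation_law(p, "c_bi", p.n["e"])))
    for y in ("r", "q"):
        stoich = {"a": -float(p.n[y]), f"c_{y}": -1, f"m_{y}": +1, "p_r": +1}
        stoich[f"p_{y}"] = stoich.get(f"p_{y}", 0) + 1
        reactions.append((f"translation_{y}", f"translation:{y}", stoich,
                          _translation_law(p, f"c_{y}", p.n[y])))
    reactions.append(("import", "import", {"s_int": +1},
                      RateLaw("linear", {"k": p.v_t * p.s}, {"s": "p_t"})))
    reactions.append(("catabolism", "catabolism",
                      {"s_int": -1, "a": +float(p.n_s)},
                      RateLaw("michaelis", {"v": p.v_m, "K": p.K_m},
                              {"e": "p_e", "s": "s_int"})))

    return _assemble(species, mass, idx, reactions, params=p)


def apply_chloramphenicol(net: ReactionNetwork, p: ParameterSet) -> ReactionNetwork:
    """Add drug inactivation ``c_y -> z_y`` at rate ``k_cm * X_cm * X_{c_y}``.

    The inactive complexes ``z_y`` retain ribosome mass but take part in no
    further reaction (they are only diluted by growth and partitioned at
    division).  Applying the extension twice is an error.
    """
    if any(name.startswith("z_") for name in net.species_names):
        raise ConfigurationError("chloramphenicol extension already applied")
    if net.rate_laws is None:
        raise ConfigurationError("drug extension requires a template-based network")
    complexes = [name for name in net.species_names if name.startswith("c_")]
    if not complexes:
        raise ConfigurationError("network has no ribosome complexes; was it built by this module?")

    species = list(net.species_names) + [f"z_{c[2:]}" for c in complexes]
    mass = {name: m for name, m in zip(net.species_names, net.mass)}
    mass.update({f"z_{c[2:]}": float(p.n["r"]) for c in complexes})
    idx = {name: i for i, name in enumerate(species)}

    reactions = []
    d = net.to_dict()
    for rx in d["reactions"]:
        reactions.append((rx["label"], rx["group"],
                          {k: v for k, v in rx["stoichiometry"].items()},
                          RateLaw(rx["rate"]["kind"], rx["rate"]["params"], rx["rate"]["species"])))
    for c in complexes:
        tag = c[2:]
        reactions.append((f"cm_inactivation_{tag}", f"cm_inactivation:{tag}",
                          {c: -1, f"z_{tag}": +1},
                          RateLaw("linear", {"k": p.k_cm * p.X_cm}, {"s": c})))

    return _assemble(species, mass, idx, reactions, params=p)


def build_model(p: ParameterSet, variant: str = "full") -> ReactionNetwork:
    """Build a model variant: ``full``, ``operon``, ``cm`` or ``operon-cm``."""
    if variant == "full":
        return build_full_model(p)
    if variant == "operon":
        return build_operon_model(p)
    if variant == "cm":
        return apply_chloramphenicol(build_full_model(p), p)
    if variant == "operon-cm":
        return apply_chloramphenicol(build_operon_model(p), p)
    raise ConfigurationError(f"unknown model variant {variant!r}")


def _assemble(species, mass, idx, reactions, params=None) -> ReactionNetwork:
    N, R = len(species), len(reactions)
    nu = np.zeros((N, R))
    laws, labels, groups = [], [], []
    for r, (label, group, stoich, law) in enumerate(reactions):
        for sp, coeff in stoich.items():
            nu[idx[sp], r] = coeff
        laws.append(law)
        labels.append(label)
        groups.append(group)
    net = ReactionNetwork(species, nu, [mass[s] for s in species], laws, labels, groups)
    net.params = params
    return net


def _sector_state(p, tag, n_rate, Xa, Xpr, Xpq, lam, g, kcm):
    """Free-mRNA and complex concentrations of one mRNA class at steady state."""
    wy = p.w["e"] if tag == "bi" else p.w[tag]
    thy = p.theta["e"] if tag == "bi" else p.theta[tag]
    dy = p.d["e"] if tag == "bi" else p.d[tag]
    om = wy * Xa / (Xa + thy) if Xa > 0 else 0.0
    if tag == "q" and p.K_q > 0:
        om /= 1.0 + (Xpq / p.K_q) ** p.h
    qy = p.k_u + g / n_rate + lam + kcm
    Xm = om / (dy + lam + p.k_b * Xpr * (lam + kcm) / qy)
    Xc = p.k_b * Xpr * Xm / qy
    return Xm, Xc


def _mrna_classes(p, operon):
    # (tag, protein length in the translation rate, mass added per event)
    if operon:
        return [("bi", p.n["e"], p.n["t"] + p.n["e"]),
                ("r", p.n["r"], p.n["r"]), ("q", p.n["q"], p.n["q"])]
    return [(y, p.n[y], p.n[y]) for y in SECTORS]


def _solve_Xpq(p, Xa, Xpr, lam, g, kcm):
    """q-protein self-consistency under negative autoregulation (1-D, monotone)."""
    from scipy.optimize import brentq

    def f(Xpq):
        _, Xc = _sector_state(p, "q", p.n["q"], Xa, Xpr, Xpq, lam, g, kcm)
        return Xpq - g * Xc / (p.n["q"] * lam)

    lo, hi = 1e-30, 1.0 / p.n["q"]
    if f(lo) >= 0:  # repression negligible at the root
        _, Xc = _sector_state(p, "q", p.n["q"], Xa, Xpr, lo, lam, g, kcm)
        return g * Xc / (p.n["q"] * lam)
    for _ in range(60):
        if f(hi) > 0:
            break
        hi *= 4.0
    return brentq(f, lo, hi, rtol=1e-13)


def _allocation(p, cls, Xa, Xpr, lam, g, kcm, operon):
    """Total mass, biomass production rate and protein levels at given unknowns."""
    Xpq = _solve_Xpq(p, Xa, Xpr, lam, g, kcm)
    total = p.n["r"] * Xpr
    mass_rate = a_cons = 0.0
    Xpt = Xpe = 0.0
    per_class = {}
    for tag, n_rate, n_mass in cls:
        Xm, Xc = _sector_state(p, tag, n_rate, Xa, Xpr, Xpq, lam, g, kcm)
        per_class[tag] = (Xm, Xc)
        total += p.n["r"] * Xc * (1.0 + (kcm / lam if kcm > 0 else 0.0))
        mass_rate += g * Xc * n_mass / n_rate
        a_cons += g * Xc
        if tag == "bi":
            Xpt = Xpe = g * Xc / (n_rate * lam)
        elif tag == "t":
            Xpt = g * Xc / (n_rate * lam)
        elif tag == "e":
            Xpe = g * Xc / (n_rate * lam)
    total += p.n["t"] * Xpt + p.n["e"] * Xpe + p.n["q"] * Xpq
    return total, mass_rate, a_cons, Xpt, Xpe, Xpq, per_class


def _solve_Xpr(p, cls, Xa, lam, g, kcm, operon):
    """Free-ribosome level closing the mass normalisation (1-D, monotone)."""
    from scipy.optimize import brentq

    def f(Xpr):
        return _allocation(p, cls, Xa, Xpr, lam, g, kcm, operon)[0] - 1.0

    lo, hi = 1e-30, 1.0 / p.n["r"]
    if f(lo) >= 0 or f(hi) <= 0:
        return None
    return brentq(f, lo, hi, rtol=1e-13)


def _growth_residual(p, cls, Xa, lam, kcm, operon):
    g = p.gamma_max * Xa / (Xa + p.K_gamma)
    Xpr = _solve_Xpr(p, cls, Xa, lam, g, kcm, operon)
    if Xpr is None:
        return None, None
    _, mass_rate, a_cons, Xpt, Xpe, Xpq, per = _allocation(p, cls, Xa, Xpr, lam, g, kcm, operon)
    return lam - mass_rate, (Xpr, Xpt, Xpe, Xpq, a_cons, per, g)


def _resource_residual(p, cls, Xa, kcm, operon, lam_hi=0.2):
    """Resource balance at the fastest-growing self-consistent allocation."""
    from scipy.optimize import brentq

    grid = np.logspace(-8, math.log10(lam_hi), 40)
    vals = [_growth_residual(p, cls, Xa, lam, kcm, operon)[0] for lam in grid]
    bracket = None
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a is not None and b is not None and a * b < 0:
            bracket = (grid[i], grid[i + 1])  # keep the last (largest-lam) crossing
    if bracket is None:
        return None, None, None
    lam = brentq(lambda L: _growth_residual(p, cls, Xa, L, kcm, operon)[0],
                 *bracket, rtol=1e-13)
    _, aux = _growth_residual(p, cls, Xa, lam, kcm, operon)
    Xpr, Xpt, Xpe, Xpq, a_cons, per, g = aux
    v_imp = p.v_t * p.s * Xpt
    b = p.v_m * Xpe + lam * p.K_m - v_imp
    Xsi = (-b + math.sqrt(b * b + 4.0 * lam * v_imp * p.K_m)) / (2.0 * lam)
    v_cat = v_imp - lam * Xsi
    return p.n_s * v_cat - a_cons - lam * Xa, lam, (Xpr, Xpt, Xpe, Xpq, Xsi, per)


def initial_guess(net: ReactionNetwork) -> "np.ndarray":
    """Starting point for the steady-state solve.

    Ribosome synthesis is autocatalytic, so generic root finding is prone
    to land on the degenerate non-growing (washout) manifold.  For networks
    built by this module the steady state nests into monotone 1-D problems
    -- q-autoregulation within mass normalisation within the growth-rate
    identity within the resource balance -- each solved by bracketing,
    which reliably selects the growing solution when one exists.
    """
    from scipy.optimize import brentq

    p = getattr(net, "params", None)
    if p is None:
        X = np.full(net.N, 1.0)
        return X / float(net.mass @ X)

    operon = "c_bi" in net.index
    kcm = p.k_cm * p.X_cm if any(n.startswith("z_") for n in net.species_names) else 0.0
    cls = _mrna_classes(p, operon)

    Xa_grid = np.logspace(-8, 4, 73)
    vals = [_resource_residual(p, cls, Xa, kcm, operon)[0] for Xa in Xa_grid]
    bracket = None
    for i in range(len(Xa_grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a is not None and b is not None and a * b < 0:
            bracket = (Xa_grid[i], Xa_grid[i + 1])
            break
    if bracket is None:
        raise ConfigurationError(
            "no growing steady state found for this parameter set"
        )
    Xa = brentq(lambda x: _resource_residual(p, cls, x, kcm, operon)[0],
                *bracket, rtol=1e-13)
    _, lam, aux = _resource_residual(p, cls, Xa, kcm, operon)
    Xpr, Xpt, Xpe, Xpq, Xsi, per = aux
    g = p.gamma_max * Xa / (Xa + p.K_gamma)

    X = np.zeros(net.N)
    idx = net.species_index
    for tag, (Xm, Xc) in per.items():
        X[idx(f"m_{tag}")] = Xm
        X[idx(f"c_{tag}")] = Xc
        if kcm > 0:
            X[idx(f"z_{tag}")] = kcm * Xc / lam
    X[idx("p_t")], X[idx("p_e")] = Xpt, Xpe
    X[idx("p_r")], X[idx("p_q")] = Xpr, Xpq
    X[idx("s_int")], X[idx("a")] = Xsi, Xa
    X = np.maximum(X, 1e-300)
    return X / float(net.mass @ X)


def require_integer_stoichiometry(net: ReactionNetwork, species: list) -> None:
    """Reject fractional stoichiometry on the given (stochastic) species.

    Non-integer nutrient quality ``n_s`` is fine for the analytic solver but
    cannot be realised as discrete reaction events.
    """
    for name in species:
        i = net.species_index(name)
        row = net.nu[i]
        if not np.allclose(row, np.round(row)):
            raise ConfigurationError(
                f"species {name!r} has non-integer stoichiometry; "
                "use an integer nutrient quality n_s for stochastic simulation"
            )
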