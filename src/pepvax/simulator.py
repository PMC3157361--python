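"""Agent-based simulation of peptide vaccination against a solid tumor.

The model is a Cartesian 3D lattice holding immune cells (helper and
cytotoxic T-cells, B-cells, macrophages, dendritic cells), cancer cells
and four molecule fields (antigen, antibody, IL-2, danger signal).  Time
advances in discrete 8-hour steps — three per day, 1095 per simulated
year.  Peptides are injected on a schedule, emulsified in adjuvant that
is modelled as a danger signal licensing macrophages and T-cell
activation; every *specific* recognition event (B-cell antigen uptake,
T-cell recognition of presented peptides, cytotoxic attack on tumor
cells) is scored with the interface-derived interaction potentials
through structure-derived contact matrices, so the whole immune response
depends explicitly on amino-acid sequences.

Recognition without a danger context drives the T-cell into anergy
instead of activation, which is what makes adjuvant-free vaccination
fail.  Activated T-cells expand clonally and seed memory; stimulated
B-cells differentiate into plasma cells whose antibodies clear antigen;
activated cytotoxic cells kill tumor cells and presenting APCs.

Per-cell rates inherited from the lattice-automaton tradition are not
published anywhere in usable form, so every such constant lives in the
:class:`Rates` table with an explicit, overridable default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from ._alphabet import encode
from .mhc_binding import Pssm, presentation_probability, score_peptide
from .potential import (
    ContactMatrix,
    InteractionPotential,
    score_to_probability,
)
from .repertoire import (
    ReceptorSequence,
    SelectionThresholds,
    generate_repertoire,
    pmhc_recognition_scores,
    thymus_select,
)

logger = logging.getLogger(__name__)

STEPS_PER_DAY = 3          # 8-hour steps
STEPS_PER_YEAR = 365 * STEPS_PER_DAY  # 1095

# cell types
TH, TC, B, MA, DC, CANCER = range(6)
TYPE_NAMES = ("TH", "TC", "B", "MA", "DC", "Cancer")

# activation states
RESTING, ACTIVE, ANERGIC, MEMORY, PRES_I, PRES_II, PLASMA, DUPLICATING = range(8)
STATE_NAMES = (
    "resting", "active", "anergic", "memory",
    "presenting_I", "presenting_II", "plasma", "duplicating",
)

MOLECULE_NAMES = ("antigen", "antibody", "il2", "danger")

CHANNELS = [f"{t}_{s}" for t in TYPE_NAMES for s in STATE_NAMES] + list(MOLECULE_NAMES)
_CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}


def build_schedule(
    start_step: int = 0, n_boosts: int = 5, interval_days: int = 28
) -> list[int]:
    """Injection steps: the initial shot plus ``n_boosts`` repeats.

    28-day intervals at three 8-hour steps per day give the default
    [0, 84, 168, 252, 336, 420].
    """
    if interval_days <= 0:
        raise ValueError("interval_days must be > 0")
    return [start_step + i * interval_days * STEPS_PER_DAY for i in range(n_boosts + 1)]


@dataclass
class Rates:
    """Every per-step rate, dose and decay constant of the model.

    All probabilities are per cell per 8-hour step.  Defaults are
    calibrated so the model reproduces the qualitative phenomenology the
    design targets: an untreated tumor doubles over one year, vaccination
    without adjuvant never activates T- or B-cells, and saturated
    recognition with adjuvant eradicates the tumor.
    """

    # geometry: lattice sites per microliter of simulated blood
    sites_per_ul: float = 1600.0
    # initial leukocyte densities per microliter, by cell type
    density_th_per_ul: float = 60.0
    density_tc_per_ul: float = 60.0
    density_b_per_ul: float = 40.0
    density_ma_per_ul: float = 20.0
    density_dc_per_ul: float = 20.0
    # receptor pool fed into thymus selection at initialization
    n_tcr_pool: int = 600
    # phagocytosis (unspecific for professional APCs)
    p_phago_dc: float = 0.5
    p_phago_ma: float = 0.5
    # presentation
    presentation_slope: float = 1.0     # logistic slope on PSSM scores
    presentation_duration: int = 6      # steps an APC keeps presenting
    p_peptide_degrade: float = 0.2      # carried peptide lost per step if not presented
    # T-cell dynamics
    p_t_duplicate: float = 0.10
    p_t_active_death: float = 0.03      # clonal contraction of active T-cells
    p_plasma_death: float = 0.02
    p_memory: float = 0.08
    il2_boost: float = 0.05             # duplication multiplier per IL-2 unit
    il2_per_th: float = 1.0             # IL-2 secreted per active TH per step
    memory_bonus: float = 2.0           # recognition-probability multiplier for memory cells
    # cytotoxicity
    p_apc_kill: float = 0.5             # active TC killing a presenting APC at its site
    # humoral arm
    p_b_stimulation: float = 0.3        # TH-stimulated B-cell differentiation
    antibody_per_plasma: float = 2.0
    antibody_clear_stoich: float = 1.0  # antigen units cleared per antibody unit
    # molecule decay per step (multiplicative) and diffusion
    decay_antigen: float = 0.995
    decay_antibody: float = 0.97
    decay_il2: float = 0.90
    decay_danger: float = 0.97
    diffuse: bool = True
    # danger signal
    danger_threshold: float = 0.05      # minimum local danger for activation context
    danger_dose_per_site: float = 160.0
    # injections
    injection_dose: float = 400.0       # antigen units per peptide per injection
    n_injection_sites: int = 25
    # tumor
    p_cancer_division: float = 2.0 ** (1.0 / STEPS_PER_YEAR) - 1.0  # doubles in a year
    # probability mapping for potential scores
    probability_strategy: str = "clamp"
    # hard cap on the immune-agent population (suppresses lymphocyte
    # division above it; tumor growth is never capped)
    max_agents: int = 8000


@dataclass
class SimulationConfig:
    """Everything one run needs: genotype, vaccine, potentials, rates, seed."""

    volume_ul: float
    initial_cancer: int
    duration: int
    schedule: list[int]
    adjuvant: bool
    seed: int
    # MHC genotype: (allele id, groove sequence) pairs
    alleles_I: list[tuple[str, str]]
    alleles_II: list[tuple[str, str]]
    # injected vaccine peptides (class I epitopes double as tumor epitopes)
    peptides_I: list[str]
    peptides_II: list[str]
    # per-allele binding matrices
    pssms_I: dict[str, Pssm]
    pssms_II: dict[str, Pssm]
    # contact template libraries: (template id, template MHC sequence, matrix)
    templates_I: list[tuple[str, str, ContactMatrix]]
    templates_II: list[tuple[str, str, ContactMatrix]]
    b_template: ContactMatrix
    # interaction potentials
    ip_t: InteractionPotential
    ip_b_high: InteractionPotential
    ip_b_low: InteractionPotential
    # thymus
    self_peptides: list[str]
    thresholds: SelectionThresholds
    rates: Rates = field(default_factory=Rates)
    ip_bias: float = 1.0

    def __post_init__(self) -> None:
        if self.volume_ul <= 0:
            raise ValueError("volume_ul must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.initial_cancer < 0:
            raise ValueError("initial_cancer must be >= 0")
        bad = [s for s in self.schedule if s > self.duration]
        if self.duration > 0 and bad:
            logger.warning("schedule steps %s fall outside the duration", bad)
        if self.ip_bias < 0:
            raise ValueError("ip_bias must be >= 0")


class TimeSeries:
    """Per-step counts for every (cell type, state) plus molecule totals."""

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[1] != len(CHANNELS):
            raise ValueError("time series shape mismatch")
        if (data < 0).any():
            raise ValueError("time series entries must be non-negative")
        self.data = data

    def __len__(self) -> int:
        return self.data.shape[0]

    def get(self, channel: str) -> np.ndarray:
        return self.data[:, _CHANNEL_INDEX[channel]]

    def cell_total(self, type_name: str) -> np.ndarray:
        cols = [i for i, c in enumerate(CHANNELS) if c.startswith(type_name + "_")]
        return self.data[:, cols].sum(axis=1)

    @property
    def cancer(self) -> np.ndarray:
        return self.cell_total("Cancer")

    @property
    def final_cancer(self) -> float:
        return float(self.cancer[-1])

    def ever_nonzero(self, channel: str) -> bool:
        return bool((self.get(channel) > 0).any())

    def to_csv(self) -> str:
        rows = ["step,channel,count"]
        for t in range(len(self)):
            for j, name in enumerate(CHANNELS):
                v = self.data[t, j]
                if v:
                    rows.append(f"{t},{name},{v!r}")
        return "\n".join(rows) + "\n"


class _Agents:
    """Struct-of-arrays agent store with amortized growth."""

    FIELDS = ("type", "state", "pos", "receptor", "carried",
              "presented", "pres_allele", "pres_timer", "age")

    def __init__(self, capacity: int = 1024):
        self.n = 0
        self._cap = capacity
        self.type = np.zeros(capacity, dtype=np.int8)
        self.state = np.zeros(capacity, dtype=np.int8)
        self.pos = np.zeros(capacity, dtype=np.int32)
        self.receptor = np.full(capacity, -1, dtype=np.int32)
        self.carried = np.full(capacity, -1, dtype=np.int16)
        self.presented = np.full(capacity, -1, dtype=np.int16)
        self.pres_allele = np.full(capacity, -1, dtype=np.int16)
        self.pres_timer = np.zeros(capacity, dtype=np.int16)
        self.age = np.zeros(capacity, dtype=np.int32)
        self.alive = np.zeros(capacity, dtype=bool)

    def _grow(self, needed: int) -> None:
        new_cap = self._cap
        while new_cap < needed:
            new_cap *= 2
        for name in self.FIELDS + ("alive",):
            old = getattr(self, name)
            new = np.zeros(new_cap, dtype=old.dtype)
            if name in ("receptor", "carried", "presented", "pres_allele"):
                new[:] = -1
            new[: self._cap] = old[: self._cap]
            setattr(self, name, new)
        self._cap = new_cap

    def add(self, cell_type: int, state: int, pos: np.ndarray | int,
            receptor: np.ndarray | int = -1) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int32))
        k = len(pos)
        if self.n + k > self._cap:
            self._grow(self.n + k)
        idx = np.arange(self.n, self.n + k)
        self.type[idx] = cell_type
        self.state[idx] = state
        self.pos[idx] = pos
        self.receptor[idx] = receptor
        self.carried[idx] = -1
        self.presented[idx] = -1
        self.pres_allele[idx] = -1
        self.pres_timer[idx] = 0
        self.age[idx] = 0
        self.alive[idx] = True
        self.n += k
        return idx

    def where(self, cell_type: int | None = None,
              states: tuple[int, ...] | None = None) -> np.ndarray:
        mask = self.alive[: self.n].copy()
        if cell_type is not None:
            mask &= self.type[: self.n] == cell_type
        if states is not None:
            mask &= np.isin(self.state[: self.n], states)
        return np.nonzero(mask)[0]

    @property
    def n_alive(self) -> int:
        return int(self.alive[: self.n].sum())


@dataclass
class LatticeState:
    """The full mutable simulation state; deterministic per config seed."""

    cfg: SimulationConfig
    side: int
    n_sites: int
    rng: np.random.Generator
    agents: _Agents
    # molecule fields
    antigen: np.ndarray        # (n_peptides, n_sites)
    antibody: np.ndarray       # (n_sites,)
    il2: np.ndarray
    danger: np.ndarray
    # peptide bookkeeping: peptides_I then peptides_II
    peptides: list[str]
    peptide_class: np.ndarray  # 1 or 2 per peptide
    # precomputed recognition probabilities (before bias)
    p_reco_I: np.ndarray       # (n_alleles_I, n_pep, n_tcr_pool)
    p_reco_II: np.ndarray      # (n_alleles_II, n_pep, n_tcr_pool)
    p_reco_B: np.ndarray       # (n_pep, n_bcr_pool)
    p_present_I: np.ndarray    # (n_alleles_I, n_pep)
    p_present_II: np.ndarray   # (n_alleles_II, n_pep)
    p_kill: np.ndarray         # (n_tcr_pool,) best tumor-epitope recognition per TCR
    n_survivors: int
    t: int = 0
    ledger: list[dict] = field(default_factory=list)

    def state_hash(self) -> int:
        a = self.agents
        parts = [getattr(a, f)[: a.n].tobytes() for f in _Agents.FIELDS]
        parts += [a.alive[: a.n].tobytes(), self.antigen.tobytes(),
                  self.antibody.tobytes(), self.il2.tobytes(), self.danger.tobytes()]
        return hash(b"".join(parts))


def _bias(p: np.ndarray | float, bias: float) -> np.ndarray | float:
    return np.minimum(1.0, np.asarray(p, dtype=float) * bias)


def initialize(cfg: SimulationConfig) -> LatticeState:
    """Build the initial lattice: tumor, leukocytes, selected repertoires.

    The lattice side is the cube root of (volume x site density), cancer
    cells are placed contiguously around the lattice center (a solid
    tumor), leukocytes uniformly at the configured densities.  The T-cell
    receptor pool is filtered through thymus selection before any cell
    receives a receptor.
    """
    r = cfg.rates
    n_sites_req = cfg.volume_ul * r.sites_per_ul
    side = max(2, int(round(n_sites_req ** (1.0 / 3.0))))
    n_sites = side ** 3
    rng = np.random.default_rng(cfg.seed)

    peptides = list(cfg.peptides_I) + list(cfg.peptides_II)
    if not peptides:
        raise ValueError("at least one injected peptide is required")
    peptide_class = np.array(
        [1] * len(cfg.peptides_I) + [2] * len(cfg.peptides_II), dtype=np.int8
    )

    # --- repertoires ---------------------------------------------------
    tcr_len = cfg.templates_I[0][2].m.shape[0]
    pool = generate_repertoire(r.n_tcr_pool, "TCR", tcr_len, rng)
    survivors = thymus_select(
        pool, cfg.self_peptides, [s for _, s in cfg.alleles_I] + [s for _, s in cfg.alleles_II],
        cfg.ip_t, list(cfg.templates_I) + list(cfg.templates_II), cfg.thresholds,
    )
    if survivors:
        tcr_codes = np.stack([encode(s.seq) for s in survivors])
    else:
        logger.warning("empty post-thymus repertoire: T-cells will carry no receptor")
        tcr_codes = np.zeros((0, tcr_len), dtype=np.uint8)

    bcr_len = cfg.b_template.m.shape[0]
    n_b = int(round(r.density_b_per_ul * cfg.volume_ul))
    bcrs = generate_repertoire(max(n_b, 1), "BCR", bcr_len, rng)
    bcr_codes = np.stack([encode(s.seq) for s in bcrs])

    # --- recognition tables --------------------------------------------
    n_pep = len(peptides)
    strategy = r.probability_strategy

    def reco_table(alleles, templates):
        out = np.zeros((len(alleles), n_pep, max(len(tcr_codes), 1)))
        if len(tcr_codes) == 0:
            return out
        for ai, (_, seq) in enumerate(alleles):
            for pi, pep in enumerate(peptides):
                scores = pmhc_recognition_scores(tcr_codes, seq, pep, templates, cfg.ip_t)
                out[ai, pi] = [score_to_probability(s, strategy) for s in scores]
        return out

    p_reco_I = reco_table(cfg.alleles_I, cfg.templates_I)
    p_reco_II = reco_table(cfg.alleles_II, cfg.templates_II)

    # B-cell recognition of each antigen peptide, glycine-split potential
    from .potential import GLYCINE_SURFACE_FREQUENCY

    p_reco_B = np.zeros((n_pep, len(bcr_codes)))
    ii, jj = np.nonzero(cfg.b_template.m)
    for pi, pep in enumerate(peptides):
        g_frac = pep.count("G") / len(pep)
        ip_b = cfg.ip_b_high if g_frac > GLYCINE_SURFACE_FREQUENCY else cfg.ip_b_low
        pep_codes = encode(pep)
        n_lig = cfg.b_template.m.shape[1]
        if len(pep_codes) < n_lig:
            pep_codes = np.tile(pep_codes, int(np.ceil(n_lig / len(pep_codes))))
        lig = pep_codes[:n_lig]
        scores = ip_b.matrix[bcr_codes[:, ii], lig[jj]].mean(axis=1)
        p_reco_B[pi] = [score_to_probability(s, strategy) for s in scores]

    # presentation probabilities per (allele, peptide), zero across classes
    def present_table(alleles, pssms, wanted_class):
        out = np.zeros((len(alleles), n_pep))
        for ai, (allele_id, _) in enumerate(alleles):
            pssm = pssms[allele_id]
            for pi, pep in enumerate(peptides):
                if peptide_class[pi] != wanted_class:
                    continue
                if len(pep) != pssm.peptide_length:
                    continue
                s = score_peptide(pssm, pep)
                out[ai, pi] = presentation_probability(s, pssm, r.presentation_slope)
        return out

    p_present_I = present_table(cfg.alleles_I, cfg.pssms_I, 1)
    p_present_II = present_table(cfg.alleles_II, cfg.pssms_II, 2)

    # cytotoxic recognition of tumor cells: best class-I epitope per TCR
    if len(tcr_codes) and len(cfg.peptides_I):
        p_kill = p_reco_I[:, : len(cfg.peptides_I), :].max(axis=(0, 1))
    else:
        p_kill = np.zeros(max(len(tcr_codes), 1))

    # --- agents ---------------------------------------------------------
    agents = _Agents()
    center = (side // 2) * (side * side + side + 1)
    # contiguous tumor: breadth-first shell around the center site
    order = np.argsort(_site_distance_to(center, side))
    tumor_sites = np.repeat(order[: max(1, math.ceil(cfg.initial_cancer / 4))], 4)
    if cfg.initial_cancer > 0:
        agents.add(CANCER, RESTING, tumor_sites[: cfg.initial_cancer])

    def seed_cells(cell_type: int, density: float, receptor_pool: int) -> None:
        count = int(round(density * cfg.volume_ul))
        if count == 0:
            return
        pos = rng.integers(0, n_sites, size=count)
        if receptor_pool > 0:
            rec = rng.integers(0, receptor_pool, size=count)
        else:
            rec = np.full(count, -1)
        agents.add(cell_type, RESTING, pos, rec)

    seed_cells(TH, r.density_th_per_ul, len(tcr_codes))
    seed_cells(TC, r.density_tc_per_ul, len(tcr_codes))
    n_b_cells = int(round(r.density_b_per_ul * cfg.volume_ul))
    if n_b_cells:
        agents.add(B, RESTING, rng.integers(0, n_sites, size=n_b_cells),
                   np.arange(n_b_cells) % len(bcr_codes))
    seed_cells(MA, r.density_ma_per_ul, 0)
    seed_cells(DC, r.density_dc_per_ul, 0)

    state = LatticeState(
        cfg=cfg, side=side, n_sites=n_sites, rng=rng, agents=agents,
        antigen=np.zeros((n_pep, n_sites)), antibody=np.zeros(n_sites),
        il2=np.zeros(n_sites), danger=np.zeros(n_sites),
        peptides=peptides, peptide_class=peptide_class,
        p_reco_I=p_reco_I, p_reco_II=p_reco_II, p_reco_B=p_reco_B,
        p_present_I=p_present_I, p_present_II=p_present_II,
        p_kill=p_kill, n_survivors=len(tcr_codes),
    )
    return state


def _site_distance_to(center: int, side: int) -> np.ndarray:
    idx = np.arange(side ** 3)
    cx, cy, cz = center // (side * side), (center // side) % side, center % side
    x, y, z = idx // (side * side), (idx // side) % side, idx % side
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2


def _move(state: LatticeState) -> None:
    """Random walk of every mobile cell to one of the 6 neighbor sites."""
    a = state.agents
    idx = np.nonzero(a.alive[: a.n] & (a.type[: a.n] != CANCER))[0]
    if len(idx) == 0:
        return
    side = state.side
    pos = a.pos[idx]
    x, y, z = pos // (side * side), (pos // side) % side, pos % side
    axis = state.rng.integers(0, 3, size=len(idx))
    delta = state.rng.choice(np.array([-1, 1]), size=len(idx))
    x = np.clip(x + np.where(axis == 0, delta, 0), 0, side - 1)
    y = np.clip(y + np.where(axis == 1, delta, 0), 0, side - 1)
    z = np.clip(z + np.where(axis == 2, delta, 0), 0, side - 1)
    a.pos[idx] = x * side * side + y * side + z


def _inject(state: LatticeState) -> None:
    cfg, r = state.cfg, state.cfg.rates
    sites = state.rng.integers(0, state.n_sites, size=r.n_injection_sites)
    per_site = r.injection_dose / r.n_injection_sites
    for pi in range(len(state.peptides)):
        np.add.at(state.antigen[pi], sites, per_site)
    if cfg.adjuvant:
        np.add.at(state.danger, sites, r.danger_dose_per_site)


def _pick_peptides(state: LatticeState, sites: np.ndarray) -> np.ndarray:
    """For each site, draw one peptide index weighted by local antigen."""
    ag = state.antigen[:, sites]              # (n_pep, k)
    totals = ag.sum(axis=0)
    out = np.full(len(sites), -1, dtype=int)
    ok = totals > 0
    if ok.any():
        cum = np.cumsum(ag[:, ok], axis=0)
        u = state.rng.random(ok.sum()) * totals[ok]
        out[ok] = (u[None, :] >= cum).sum(axis=0)
    return out


def _representative_at_sites(
    state: LatticeState, candidate_idx: np.ndarray, query_sites: np.ndarray
) -> np.ndarray:
    """One random candidate agent per query site (-1 when none is there).

    Candidate order is permuted per step, implementing random resolution
    of simultaneous conflicts.
    """
    out = np.full(len(query_sites), -1, dtype=int)
    if len(candidate_idx) == 0 or len(query_sites) == 0:
        return out
    perm = state.rng.permutation(len(candidate_idx))
    cand = candidate_idx[perm]
    cand_sites = state.agents.pos[cand]
    order = np.argsort(cand_sites, kind="stable")
    cand = cand[order]
    cand_sites = cand_sites[order]
    pos = np.searchsorted(cand_sites, query_sites)
    ok = (pos < len(cand_sites)) & (cand_sites[np.minimum(pos, len(cand_sites) - 1)] == query_sites)
    out[ok] = cand[pos[ok]]
    return out


def _phagocytosis(state: LatticeState, births: dict, deaths: dict) -> None:
    """Unspecific uptake by DCs and danger-activated macrophages; B-cells
    must recognize the antigen through the B-cell potential to ingest it."""
    a, r = state.agents, state.cfg.rates
    bias = state.cfg.ip_bias

    # macrophage activation by the danger signal (adjuvant)
    ma_rest = a.where(MA, (RESTING,))
    if len(ma_rest):
        hot = state.danger[a.pos[ma_rest]] >= r.danger_threshold
        a.state[ma_rest[hot]] = ACTIVE

    for cell_type, prob, states in (
        (DC, r.p_phago_dc, (RESTING,)),
        (MA, r.p_phago_ma, (ACTIVE,)),
    ):
        idx = a.where(cell_type, states)
        idx = idx[a.carried[idx] < 0]
        if len(idx) == 0:
            continue
        take = state.rng.random(len(idx)) < prob
        idx = idx[take]
        peps = _pick_peptides(state, a.pos[idx])
        got = peps >= 0
        idx, peps = idx[got], peps[got]
        a.carried[idx] = peps
        np.subtract.at(state.antigen, (peps, a.pos[idx]), 1.0)
        np.clip(state.antigen, 0.0, None, out=state.antigen)

    # B-cells: specific recognition gates ingestion
    b_idx = a.where(B, (RESTING,))
    b_idx = b_idx[a.carried[b_idx] < 0]
    if len(b_idx):
        peps = _pick_peptides(state, a.pos[b_idx])
        got = peps >= 0
        b_idx, peps = b_idx[got], peps[got]
        if len(b_idx):
            p = _bias(state.p_reco_B[peps, a.receptor[b_idx]], bias)
            hit = state.rng.random(len(b_idx)) < p
            b_idx, peps = b_idx[hit], peps[hit]
            a.carried[b_idx] = peps
            a.state[b_idx] = ACTIVE
            np.subtract.at(state.antigen, (peps, a.pos[b_idx]), 1.0)
            np.clip(state.antigen, 0.0, None, out=state.antigen)


def _presentation(state: LatticeState) -> None:
    """Carried peptides go onto MHC with the PSSM-derived probability."""
    a, r = state.agents, state.cfg.rates
    cfg = state.cfg

    for cell_type, can_I, can_II in ((DC, True, True), (MA, False, True), (B, False, True)):
        idx = a.where(cell_type)
        idx = idx[(a.carried[idx] >= 0) & (a.state[idx] != PRES_I) & (a.state[idx] != PRES_II)]
        if len(idx) == 0:
            continue
        peps = a.carried[idx]
        cls = state.peptide_class[peps]
        for wanted, can, table, alleles, new_state in (
            (1, can_I, state.p_present_I, cfg.alleles_I, PRES_I),
            (2, can_II, state.p_present_II, cfg.alleles_II, PRES_II),
        ):
            if not can or len(alleles) == 0:
                continue
            sel = np.nonzero(cls == wanted)[0]
            if len(sel) == 0:
                continue
            sub = idx[sel]
            allele_pick = state.rng.integers(0, len(alleles), size=len(sub))
            p = table[allele_pick, peps[sel]]
            ok = state.rng.random(len(sub)) < p
            win = sub[ok]
            a.state[win] = new_state
            a.presented[win] = peps[sel][ok]
            a.pres_allele[win] = allele_pick[ok]
            a.pres_timer[win] = r.presentation_duration
            a.carried[win] = -1

    # unpresented carried peptides degrade
    carrying = np.nonzero(a.alive[: a.n] & (a.carried[: a.n] >= 0))[0]
    if len(carrying):
        lost = state.rng.random(len(carrying)) < r.p_peptide_degrade
        a.carried[carrying[lost]] = -1

    # presentation expires
    presenting = a.where(None, (PRES_I, PRES_II))
    if len(presenting):
        a.pres_timer[presenting] -= 1
        done = presenting[a.pres_timer[presenting] <= 0]
        a.state[done] = np.where(a.type[done] == B, ACTIVE, RESTING)
        a.presented[done] = -1
        a.pres_allele[done] = -1


def _t_recognition(state: LatticeState, births: dict, deaths: dict) -> None:
    """T-cells recognize presented peptides; danger decides activation
    versus anergy."""
    a, r = state.agents, state.cfg.rates
    bias = state.cfg.ip_bias

    for t_type, pres_state, table in (
        (TC, PRES_I, state.p_reco_I),
        (TH, PRES_II, state.p_reco_II),
    ):
        apcs = a.where(None, (pres_state,))
        apcs = apcs[a.type[apcs] != CANCER]
        t_idx = a.where(t_type, (RESTING, MEMORY))
        t_idx = t_idx[a.receptor[t_idx] >= 0]
        if len(apcs) == 0 or len(t_idx) == 0:
            continue
        partner = _representative_at_sites(state, apcs, a.pos[t_idx])
        met = partner >= 0
        t_idx, partner = t_idx[met], partner[met]
        if len(t_idx) == 0:
            continue
        pep = a.presented[partner]
        allele = a.pres_allele[partner]
        p = table[allele, pep, a.receptor[t_idx]]
        is_memory = a.state[t_idx] == MEMORY
        p = np.where(is_memory, p * r.memory_bonus, p)
        p = _bias(p, bias)
        hit = state.rng.random(len(t_idx)) < p
        t_hit = t_idx[hit]
        if len(t_hit) == 0:
            continue
        danger_ok = state.danger[a.pos[t_hit]] >= r.danger_threshold
        a.state[t_hit[danger_ok]] = ACTIVE
        # recognition without co-stimulation: anergy (absorbing)
        cold = t_hit[~danger_ok]
        cold = cold[a.state[cold] != MEMORY]  # memory cells stay memory
        a.state[cold] = ANERGIC


def _clonal_expansion(state: LatticeState, births: dict) -> None:
    a, r = state.agents, state.cfg.rates
    if a.n_alive >= r.max_agents:
        return
    for t_type in (TC, TH):
        idx = a.where(t_type, (ACTIVE,))
        if len(idx) == 0:
            continue
        boost = 1.0 + r.il2_boost * state.il2[a.pos[idx]]
        p = np.minimum(1.0, r.p_t_duplicate * boost)
        dup = state.rng.random(len(idx)) < p
        parents = idx[dup]
        room = max(0, r.max_agents - a.n_alive)
        parents = parents[:room]
        if len(parents) == 0:
            continue
        a.add(t_type, ACTIVE, a.pos[parents], a.receptor[parents])
        births["division"] = births.get("division", 0) + len(parents)
        mem = parents[state.rng.random(len(parents)) < r.p_memory]
        if len(mem):
            a.add(t_type, MEMORY, a.pos[mem], a.receptor[mem])
            births["memory"] = births.get("memory", 0) + len(mem)
    # active TH secrete IL-2
    th_active = a.where(TH, (ACTIVE,))
    if len(th_active):
        np.add.at(state.il2, a.pos[th_active], r.il2_per_th)


def _cytotoxicity(state: LatticeState, births: dict, deaths: dict) -> None:
    """Active TC kill tumor cells (potential-scored) and presenting APCs."""
    a, r = state.agents, state.cfg.rates
    bias = state.cfg.ip_bias
    tc_active = a.where(TC, (ACTIVE,))
    tc_active = tc_active[a.receptor[tc_active] >= 0]
    if len(tc_active) == 0:
        return
    # per-site survival aggregation over every attacking TC
    p_each = _bias(state.p_kill[a.receptor[tc_active]], bias)
    p_each = np.clip(p_each, 0.0, 1.0 - 1e-12)
    site_log = np.zeros(state.n_sites)
    np.add.at(site_log, a.pos[tc_active], np.log1p(-p_each))
    cancer = a.where(CANCER)
    if len(cancer):
        p_die = 1.0 - np.exp(site_log[a.pos[cancer]])
        dead = cancer[state.rng.random(len(cancer)) < p_die]
        a.alive[dead] = False
        deaths["cancer_killed"] = deaths.get("cancer_killed", 0) + len(dead)
    # presenting APCs are killed by activated TC at the same site
    n_tc_site = np.bincount(a.pos[tc_active], minlength=state.n_sites)
    apcs = a.where(None, (PRES_I, PRES_II))
    if len(apcs):
        k = n_tc_site[a.pos[apcs]]
        p_die = 1.0 - (1.0 - r.p_apc_kill) ** k
        dead = apcs[state.rng.random(len(apcs)) < p_die]
        a.alive[dead] = False
        deaths["apc_killed"] = deaths.get("apc_killed", 0) + len(dead)


def _humoral(state: LatticeState, births: dict) -> None:
    """TH-stimulated B-cells spawn plasma and memory cells; plasma secrete
    antibodies; antibodies clear antigen."""
    a, r = state.agents, state.cfg.rates
    th_active = a.where(TH, (ACTIVE,))
    b_ready = a.where(B, (ACTIVE, PRES_II))
    if len(th_active) and len(b_ready) and a.n_alive < r.max_agents:
        n_th_site = np.bincount(a.pos[th_active], minlength=state.n_sites)
        helped = b_ready[n_th_site[a.pos[b_ready]] > 0]
        stim = helped[state.rng.random(len(helped)) < r.p_b_stimulation]
        room = max(0, r.max_agents - a.n_alive)
        stim = stim[: room // 2]
        if len(stim):
            a.add(B, PLASMA, a.pos[stim], a.receptor[stim])
            a.add(B, MEMORY, a.pos[stim], a.receptor[stim])
            births["b_differentiation"] = births.get("b_differentiation", 0) + 2 * len(stim)
    plasma = a.where(B, (PLASMA,))
    if len(plasma):
        np.add.at(state.antibody, a.pos[plasma], r.antibody_per_plasma)
    # antibody-mediated antigen clearance, proportional across peptides
    total = state.antigen.sum(axis=0)
    cleared = np.minimum(total, state.antibody * r.antibody_clear_stoich)
    mask = total > 0
    if mask.any():
        frac = np.zeros_like(total)
        frac[mask] = cleared[mask] / total[mask]
        state.antigen *= 1.0 - frac[None, :]
        state.antibody = np.maximum(0.0, state.antibody - cleared)


def _death(state: LatticeState, deaths: dict) -> None:
    """Clonal contraction: activated effector cells die at a constant rate."""
    a, r = state.agents, state.cfg.rates
    for idx, p, label in (
        (np.concatenate([a.where(TC, (ACTIVE,)), a.where(TH, (ACTIVE,))]),
         r.p_t_active_death, "t_contraction"),
        (a.where(B, (PLASMA,)), r.p_plasma_death, "plasma_death"),
    ):
        if len(idx) == 0 or p <= 0:
            continue
        gone = idx[state.rng.random(len(idx)) < p]
        if len(gone):
            a.alive[gone] = False
            deaths[label] = deaths.get(label, 0) + len(gone)


def _cancer_division(state: LatticeState, births: dict) -> None:
    # deliberately not subject to the immune-agent cap: unlimited growth is
    # the untreated baseline
    a, r = state.agents, state.cfg.rates
    cancer = a.where(CANCER)
    if len(cancer) == 0:
        return
    div = cancer[state.rng.random(len(cancer)) < r.p_cancer_division]
    if len(div):
        a.state[div] = DUPLICATING
        a.add(CANCER, RESTING, a.pos[div])
        births["cancer_division"] = births.get("cancer_division", 0) + len(div)
        a.state[div] = RESTING


def _decay_and_diffuse(state: LatticeState) -> None:
    r = state.cfg.rates
    shape = (state.side,) * 3

    def smooth(f: np.ndarray) -> np.ndarray:
        if not r.diffuse:
            return f
        return ndimage.uniform_filter(f.reshape(shape), size=3, mode="nearest").ravel()

    state.antigen = np.stack([smooth(state.antigen[i]) for i in range(state.antigen.shape[0])]) * r.decay_antigen
    state.antibody = smooth(state.antibody) * r.decay_antibody
    state.il2 = smooth(state.il2) * r.decay_il2
    state.danger = smooth(state.danger) * r.decay_danger
    for f in (state.antigen, state.antibody, state.il2, state.danger):
        np.clip(f, 0.0, None, out=f)


def _record(state: LatticeState) -> np.ndarray:
    a = state.agents
    row = np.zeros(len(CHANNELS))
    alive = np.nonzero(a.alive[: a.n])[0]
    if len(alive):
        combo = a.type[alive].astype(int) * len(STATE_NAMES) + a.state[alive]
        counts = np.bincount(combo, minlength=len(TYPE_NAMES) * len(STATE_NAMES))
        row[: len(counts)] = counts
    row[_CHANNEL_INDEX["antigen"]] = state.antigen.sum()
    row[_CHANNEL_INDEX["antibody"]] = state.antibody.sum()
    row[_CHANNEL_INDEX["il2"]] = state.il2.sum()
    row[_CHANNEL_INDEX["danger"]] = state.danger.sum()
    return row


def step(state: LatticeState) -> LatticeState:
    """Advance the lattice by one 8-hour step (in place; returns state).

    Phase order: injection, movement, phagocytosis, presentation, T-cell
    recognition, clonal expansion, cytotoxicity, humoral response, tumor
    division, molecule decay.
    """
    births: dict = {}
    deaths: dict = {}
    alive_before = state.agents.n_alive
    state.t += 1
    # an injection scheduled for step s happens while advancing from s to s+1
    if state.t - 1 in state.cfg.schedule:
        _inject(state)
    _move(state)
    _phagocytosis(state, births, deaths)
    _presentation(state)
    _t_recognition(state, births, deaths)
    _clonal_expansion(state, births)
    _cytotoxicity(state, births, deaths)
    _humoral(state, births)
    _death(state, deaths)
    _cancer_division(state, births)
    _decay_and_diffuse(state)
    state.agents.age[: state.agents.n][state.agents.alive[: state.agents.n]] += 1
    state.ledger.append(
        {
            "t": state.t,
            "alive_before": alive_before,
            "births": births,
            "deaths": deaths,
            "alive_after": state.agents.n_alive,
        }
    )
    return state


def run(cfg: SimulationConfig) -> TimeSeries:
    """Initialize and advance ``cfg.duration`` steps; returns the series."""
    state = initialize(cfg)
    rows = [_record(state)]
    for _ in range(cfg.duration):
        step(state)
        rows.append(_record(state))
    ts = TimeSeries(np.asarray(rows))
    ts.ledger = state.ledger  # type: ignore[attr-defined]
    ts.n_survivors = state.n_survivors  # type: ignore[attr-defined]
    return ts


def reactiveness(treated: TimeSeries, untreated: TimeSeries) -> float:
    """Percent tumor reduction versus unlimited growth; 100 = eradication."""
    if len(treated) != len(untreated):
        raise ValueError("series must cover equal durations")
    denom = untreated.final_cancer
    if denom == 0:
        raise ValueError("untreated final cancer count is zero; reactiveness undefined")
    return max(0.0, 100.0 * (1.0 - treated.final_cancer / denom))


def classify_outcome(series: TimeSeries, initial_cancer: int) -> str:
    """'success' iff the final tumor is strictly smaller than at start."""
    return "success" if series.final_cancer < initial_cancer else "failure"


FAILURE_CHANNELS = (
    "TC_active", "TH_active", "DC_presenting_I", "DC_presenting_II", "MA_presenting_II",
)


def failure_profile(
    runs: Sequence[tuple[TimeSeries, str]],
) -> tuple[dict[str, float], str]:
    """Activation-state propensities among failing runs, plus the group.

    For every failing run, each population channel is scored present if it
    was ever non-zero; the propensity is the fraction of failing runs with
    the population present.  Runs are grouped as ``frequent_failures``
    when the overall success rate is below 50% and ``rare_failures``
    otherwise.
    """
    if not runs:
        raise ValueError("no runs given")
    n_success = sum(1 for _, outcome in runs if outcome == "success")
    group = "rare_failures" if n_success / len(runs) >= 0.5 else "frequent_failures"
    failures = [ts for ts, outcome in runs if outcome != "success"]
    if not failures:
        return {}, group
    table = {
        ch: sum(1 for ts in failures if ts.ever_nonzero(ch)) / len(failures)
        for ch in FAILURE_CHANNELS
    }
    return table, group


def bias_sweep(
    cfg: SimulationConfig,
    factors: Sequence[float],
    replicates: int = 20,
) -> list[dict[str, float]]:
    """Scale every potential-derived probability and rerun the simulation.

    For each multiplicative factor, ``replicates`` runs with distinct
    seeds are summarized by the mean final tumor size relative to the
    initial size, the mean number of steps until the tumor first drops
    below its initial size (NaN when no run reduces it), and the success
    fraction.
    """
    if any(f < 0 for f in factors):
        raise ValueError("factors must be >= 0")
    out = []
    for fi, factor in enumerate(factors):
        finals, steps_to_red, successes = [], [], 0
        for rep in range(replicates):
            c = replace(cfg, ip_bias=cfg.ip_bias * factor, seed=cfg.seed + 1000 * fi + rep)
            ts = run(c)
            finals.append(ts.final_cancer / max(cfg.initial_cancer, 1))
            below = np.nonzero(ts.cancer < cfg.initial_cancer)[0]
            if len(below):
                steps_to_red.append(int(below[0]))
            if classify_outcome(ts, cfg.initial_cancer) == "success":
                successes += 1
        out.append(
            {
                "factor": float(factor),
                "mean_relative_final_tumor": float(np.mean(finals)),
                "mean_steps_to_reduction": float(np.mean(steps_to_red)) if steps_to_red else float("nan"),
                "success_fraction": successes / replicates,
            }
        )
    return out
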