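"""Synthetic two-mitotype mitogenome datasets.

Generates a codon-valid reference genome on the default template and
evolves two clades from it: Poisson-distributed substitutions on a single
between-mitotype branch and on independent per-sample branches (a star
genealogy), followed by optional heteroplasmy (two-base IUPAC symbols).

Selection is modelled through acceptance of proposed changes: a proposed
CDS change is realised as nonsynonymous with the element's per-complex
probability and as synonymous otherwise (requiring a synonymous single-base
neighbour); proposals in structural RNA genes are accepted with a reduced
probability.  Rejected proposals are re-drawn elsewhere, so the realised
genome-wide divergence matches the requested rate while low-omega elements
accumulate fewer changes.

``d_between`` is the expected realised per-site divergence between samples
of different mitotypes, so the between-branch rate is reduced by the two
within-clade branch contributions.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import InputError
from .mitomodel import (
    CDS,
    LabeledAlignment,
    MitogenomeModel,
    VERTEBRATE_MITO,
    default_model,
    write_alignment,
    write_gff3,
    write_sample_sheet,
)
from .mitomodel import iupac
from .mitomodel.genetic_code import NONSYNONYMOUS, SYNONYMOUS
from .mitomodel.model import RRNA, TRNA

_BASES = "ACGT"

DEFAULT_OMEGA = {"I": 0.35, "III": 0.15, "IV": 0.05, "V": 0.05}

CLASS_NONCODING = "noncoding"
CLASS_UNCONSTRAINED = "unconstrained"  # intergenic / control / trailing bases


@dataclass
class SimulationConfig:
    """All generator knobs.  Defaults reproduce the published divergence
    band (0.032-0.034 between mitotypes) with Complex-I-skewed selection."""

    seed: int = 0
    n_tnp: int = 6
    n_ena: int = 6
    d_between: float = 0.033
    theta_within: float = 0.002
    omega_by_complex: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OMEGA)
    )
    noncoding_accept: float = 0.4
    het_rate: float = 0.0
    control_region: bool = False
    include_reference: bool = True

    def __post_init__(self) -> None:
        for name in ("d_between", "theta_within", "noncoding_accept", "het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if self.n_tnp < 0 or self.n_ena < 0:
            raise InputError("sample sizes must be nonnegative")
        omega = dict(DEFAULT_OMEGA)
        omega.update(self.omega_by_complex)
        for cx, v in omega.items():
            if not 0.0 <= v <= 1.0:
                raise InputError(f"omega for complex {cx} must be in [0, 1]")
        self.omega_by_complex = omega

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        return cls(**data)


@dataclass
class SimulatedDataset:
    alignment: LabeledAlignment
    model: MitogenomeModel
    reference: str
    truth: dict


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

def _random_cds(length: int, rng: np.random.Generator) -> str:
    """A codon-valid coding sequence: ATG start, sense body, TAA stop when
    the length is a codon multiple, otherwise a T/TA incomplete stop."""
    sense = VERTEBRATE_MITO.sense_codons()
    n_full, rem = divmod(length, 3)
    if rem == 0:
        body = rng.integers(0, len(sense), size=n_full - 2)
        return "ATG" + "".join(sense[i] for i in body) + "TAA"
    body = rng.integers(0, len(sense), size=n_full - 1)
    return "ATG" + "".join(sense[i] for i in body) + "TA"[:rem]


def make_reference(
    seed: int, include_control_region: bool = False
) -> tuple[MitogenomeModel, str]:
    """Deterministic reference genome on the default 37-element template.

    Every CDS starts with ATG, contains no internal stop under the
    vertebrate mitochondrial code and ends with a (possibly incomplete)
    stop codon; minus-strand CDSs are stored reverse-complemented.
    """
    rng = np.random.default_rng(seed)
    model = default_model(include_control_region=include_control_region)
    seq = list(rng.choice(list(_BASES), size=model.sequence_length))
    for e in model.elements:
        if e.kind != CDS:
            continue
        coding = _random_cds(e.length, rng)
        if e.strand == "-":
            coding = iupac.reverse_complement(coding)
        seq[e.start : e.end] = coding
    return model, "".join(seq)


# ---------------------------------------------------------------------------
# Mutation machinery
# ---------------------------------------------------------------------------

class _SiteMap:
    """Per-site element lookup plus codon bookkeeping for CDS sites."""

    def __init__(self, model: MitogenomeModel):
        self.length = model.sequence_length
        self.element = [None] * model.sequence_length
        for e in model.elements:
            for c in range(e.start, e.end):
                self.element[c] = e

    def coding_pos(self, e, site: int) -> int:
        return site - e.start if e.strand == "+" else e.end - 1 - site

    def codon_at(self, seq: list[str], e, site: int):
        """(codon string on the coding strand, position within codon) or
        None for trailing incomplete-codon bases."""
        p = self.coding_pos(e, site)
        n_full = e.length // 3
        if p // 3 >= n_full:
            return None
        start = p - p % 3
        if e.strand == "+":
            g0 = e.start + start
            codon = "".join(seq[g0 : g0 + 3])
        else:
            g0 = e.end - start - 3
            codon = iupac.reverse_complement("".join(seq[g0 : g0 + 3]))
        return codon, p % 3, p // 3, n_full

    def is_terminal_codon(self, e, codon_index: int, n_full: int) -> bool:
        return codon_index == n_full - 1 and e.length % 3 == 0


def _propose(site_map, seq, site, rng, omega_by_complex, noncoding_accept):
    """Attempt a substitution at ``site``; returns (alt_char, class) or
    None when the proposal is rejected (caller re-draws a site)."""
    e = site_map.element[site]
    code = VERTEBRATE_MITO
    if e is None or e.kind not in (CDS, TRNA, RRNA):
        cur = seq[site]
        choices = [b for b in _BASES if b != cur]
        return choices[int(rng.integers(3))], CLASS_UNCONSTRAINED
    if e.kind in (TRNA, RRNA):
        if rng.random() >= noncoding_accept:
            return None
        cur = seq[site]
        choices = [b for b in _BASES if b != cur]
        return choices[int(rng.integers(3))], CLASS_NONCODING
    # CDS
    ctx = site_map.codon_at(seq, e, site)
    if ctx is None:
        cur = seq[site]
        choices = [b for b in _BASES if b != cur]
        return choices[int(rng.integers(3))], CLASS_UNCONSTRAINED
    codon, pos, codon_index, n_full = ctx
    terminal = site_map.is_terminal_codon(e, codon_index, n_full)
    omega = omega_by_complex[e.complex]
    want_nonsyn = rng.random() < omega
    if want_nonsyn:
        # never create a stop inside the frame; never destroy the terminal stop
        if terminal and code.is_stop(codon):
            return None
        alts = code.nonsynonymous_alternatives(codon, pos, exclude_stops=not terminal)
        klass = NONSYNONYMOUS
    else:
        alts = code.synonymous_alternatives(codon, pos)
        klass = SYNONYMOUS
    if not alts:
        return None
    alt = alts[int(rng.integers(len(alts)))]
    if e.strand == "-":
        alt = iupac.COMPLEMENT[alt]
    return alt, klass


def _mutate_branch(
    seq: list[str],
    n_subs: int,
    rng: np.random.Generator,
    site_map: _SiteMap,
    config: SimulationConfig,
    branch: str,
    events: list[dict],
) -> None:
    """Place exactly ``n_subs`` accepted substitutions on a branch.

    Sites are drawn uniformly; proposals the selection model cannot realise
    (no synonymous neighbour, rejected RNA change) are re-drawn at a fresh
    site, never recorded inconsistently.
    """
    used: set[int] = set()
    budget = 200 * (n_subs + 50)
    placed = 0
    while placed < n_subs:
        budget -= 1
        if budget <= 0:
            raise InputError(
                f"cannot place {n_subs} substitutions on branch {branch!r}; "
                "rates are inconsistent with the selection model"
            )
        site = int(rng.integers(site_map.length))
        if site in used:
            continue
        result = _propose(
            site_map, seq, site, rng, config.omega_by_complex, config.noncoding_accept
        )
        if result is None:
            continue
        alt, klass = result
        e = site_map.element[site]
        events.append(
            {
                "branch": branch,
                "site": site,
                "element": e.name if e is not None else None,
                "class": klass,
                "from": seq[site],
                "to": alt,
            }
        )
        seq[site] = alt
        used.add(site)
        placed += 1


def _apply_heteroplasmy(
    seq: list[str], rng: np.random.Generator, het_rate: float
) -> list[dict]:
    if het_rate <= 0:
        return []
    hits = np.nonzero(rng.random(len(seq)) < het_rate)[0]
    out = []
    for site in hits:
        cur = seq[site]
        if cur not in _BASES:
            continue  # already ambiguous (cannot happen: applied last)
        choices = [b for b in _BASES if b != cur]
        alt = choices[int(rng.integers(3))]
        sym = iupac.ambiguity_symbol({cur, alt})
        seq[site] = sym
        out.append({"site": int(site), "symbol": sym})
    return out


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a two-clade dataset; all randomness flows from the config
    seed, so equal configs give byte-identical outputs."""
    model, reference = make_reference(
        config.seed, include_control_region=config.control_region
    )
    rng = np.random.default_rng([config.seed, 0x6D69746F])  # seed stream for evolution
    site_map = _SiteMap(model)
    length = model.sequence_length

    events: list[dict] = []

    # Between-mitotype branch: calibrated so the expected *pairwise*
    # between-mitotype distance equals d_between.
    branch_rate = max(0.0, config.d_between - 2.0 * config.theta_within)
    n_between = int(rng.poisson(branch_rate * length))
    tnp_ancestor = list(reference)
    ena_ancestor = list(reference)
    _mutate_branch(ena_ancestor, n_between, rng, site_map, config, "between", events)

    ids, seqs = [], []
    mitotypes, populations = {}, {}
    heteroplasmy: dict[str, list[dict]] = {}

    if config.include_reference:
        ids.append("TNP_REF")
        seqs.append(reference)
        mitotypes["TNP_REF"] = "TNP"
        populations["TNP_REF"] = "reference"

    clades = [("TNP", tnp_ancestor, config.n_tnp), ("ENA", ena_ancestor, config.n_ena)]
    for mitotype, ancestor, n in clades:
        for k in range(1, n + 1):
            sid = f"{mitotype}_{k:02d}"
            sample = list(ancestor)
            m = int(rng.poisson(config.theta_within * length))
            _mutate_branch(sample, m, rng, site_map, config, sid, events)
            het = _apply_heteroplasmy(sample, rng, config.het_rate)
            if het:
                heteroplasmy[sid] = het
            ids.append(sid)
            seqs.append("".join(sample))
            mitotypes[sid] = mitotype
            populations[sid] = f"pop-{mitotype}"

    alignment = LabeledAlignment(
        ids=ids, seqs=seqs, mitotypes=mitotypes, populations=populations
    )

    between_per_element: dict[str, int] = {}
    between_classes: dict[str, dict[str, int]] = {}
    for ev in events:
        if ev["branch"] != "between":
            continue
        name = ev["element"] or "intergenic"
        between_per_element[name] = between_per_element.get(name, 0) + 1
        cls = between_classes.setdefault(name, {})
        cls[ev["class"]] = cls.get(ev["class"], 0) + 1

    truth = {
        "config": asdict(config),
        "genome_length": length,
        "ancestors": {"TNP": "".join(tnp_ancestor), "ENA": "".join(ena_ancestor)},
        "n_between": n_between,
        "between_per_element": between_per_element,
        "between_classes": between_classes,
        "events": events,
        "heteroplasmy": heteroplasmy,
    }
    return SimulatedDataset(
        alignment=alignment, model=model, reference=reference, truth=truth
    )


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write aligned FASTA, GFF3, sample sheet and truth JSON; the FASTA and
    sheet round-trip through ``load_alignment``."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "alignment": write_alignment(dataset.alignment, out / "alignment.fasta"),
            "annotation": write_gff3(dataset.model, out / "annotation.gff3"),
            "samples": write_sample_sheet(dataset.alignment, out / "samples.tsv"),
            "truth": out / "truth.json",
        }
        with open(paths["truth"], "w") as fh:
            json.dump(dataset.truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise InputError(f"cannot write dataset under {out}: {exc}") from exc
    return paths
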