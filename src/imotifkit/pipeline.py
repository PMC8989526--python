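"""End-to-end reproduction workflows over synthetic fixtures.

Each function here builds a seeded synthetic fixture at the study's stated
conditions, runs the corresponding analysis stage, and returns the measured
quantity.  ``run_reproduction_workflow`` composes them all into one summary dict.

Study conditions encoded here (see also docs/methods.md):

* titrations: pH 5.0-8.0 in 0.25 steps, 2% amplitude noise, 3 replicates,
  Hill slope 1.5, midpoints 7.1 (d(TCCC)9) and 6.7 (d(TCCC)5);
* melting: noise-free two-state curves on a 4-95 degC, 1 degC grid, folding
  enthalpy -40 kcal/mol, flat baselines, midpoints 40.7 degC (pH 6.5) and
  66.7 degC (pH 5.3) for d(TCCC)9;
* bisulfite: 200 bp reference regions, 500 clones at per-cytosine element
  conversion rate 0.374, and deterministic 27-clone deletion fixtures;
* mass spectrum: 5000 molecules of the 36mer, 27 cytosines, conversion
  probability 0.33, 8% fragment abundance;
* suppression: p = 0.05 per cycle over 25 cycles.
"""

from __future__ import annotations

import numpy as np

from . import bisulfite, massdist, melting, repeats, synthetic, titration
from .deletion_model import SuppressionModel, impairment_probability, profile_association
from .tables import published_length_profile

__all__ = [
    "child_seed",
    "recover_ph_t",
    "recover_tm",
    "recover_conversion_pct",
    "deletion_pct_upstream_fixture",
    "deletion_pct_overlap_fixture",
    "mass_mode",
    "intact_pct",
    "run_reproduction_workflow",
]

PH_T_9 = 7.1
PH_T_5 = 6.7
TM_9_PH65 = 40.7
TM_9_PH53 = 66.7
CONVERSION_RATE_9 = 0.374
DU_P_CONVERT = 0.33
N_CYTOSINES_36MER = 27
FRAGMENT_FRACTION = 0.08
SUPPRESSION = SuppressionModel(p_unsuppressed=0.05, cycles=25)


def child_seed(base_seed: int, stream: int) -> int:
    """Mix a base seed with a per-fixture stream id; stays below 2^31."""
    return (base_seed * 100_003 + stream) % (2**31 - 1)


def recover_ph_t(true_ph_t: float, seed: int, noise_sd: float = 0.02,
                 n_replicates: int = 3, hill: float = 1.5) -> float:
    """Generate replicate titrations at a known midpoint and re-fit it."""
    cfg = synthetic.SimConfig(seed=seed, noise_sd=noise_sd,
                              n_replicates=n_replicates)
    series = [synthetic.gen_titration(ph_t=true_ph_t, hill=hill, cfg=cfg,
                                      replicate_id=r)
              for r in range(n_replicates)]
    return titration.fit_titration(series).ph_t


def recover_tm(true_tm: float, dh: float = -40.0, window: int = 5) -> float:
    """Generate a noise-free two-state melt curve and re-derive its midpoint."""
    curve = synthetic.gen_melt_curve(tm=true_tm, dh=dh,
                                     cfg=synthetic.SimConfig(seed=0))
    est = melting.first_derivative_midpoint(curve, window=window)
    if est is None:
        raise RuntimeError("no transition detected on a generated curve")
    return est


def _reference_with_element(n_units: int, seed: int, length: int = 200,
                            element_start: int = 100) -> bisulfite.ReferenceRegion:
    sim = synthetic.gen_genome(
        length, planted=[(element_start, "TCCC", n_units)],
        cfg=synthetic.SimConfig(seed=seed))
    elements = [el for el in repeats.find_elements(sim.sequence, min_n=n_units)
                if el.start <= element_start < el.end and el.c_rich_strand == "+"]
    return bisulfite.ReferenceRegion(id=f"region_tccc{n_units}",
                                     sequence=sim.sequence, elements=elements)


def recover_conversion_pct(rate: float = CONVERSION_RATE_9, seed: int = 7,
                           n_clones: int = 500) -> float:
    """Element C->T conversion percentage on synthetic d(TCCC)9 clones.

    Clones are generated with every element cytosine independently converted
    at ``rate`` (background duplex cytosines near-inert), aligned in
    bisulfite mode, and the element-scoped conversion frequency recalled.
    """
    ref = _reference_with_element(9, seed=child_seed(seed, 91))
    rates = synthetic.BisulfiteRates(p_cc_plus=rate)
    clone_set = synthetic.gen_clone_set(ref, n_clones=n_clones, rates=rates,
                                        cfg=synthetic.SimConfig(seed=seed))
    alns = [bisulfite.align_clone(ref, seq, clone_id=cid)
            for cid, seq in clone_set.clones]
    stats = bisulfite.call_conversions(alns, element=ref.elements[0],
                                       scope="element")
    return 100.0 * stats.frequency


def deletion_pct_upstream_fixture(seed: int = 3, n_clones: int = 27,
                                  n_deleted: int = 5) -> float:
    """Deletion percentage on a fixture with planted upstream deletions.

    ``n_deleted`` of ``n_clones`` clones of a d(TCCC)5 region carry an 8 bp
    deletion starting 12 bp 5' of the element; the rest are intact.
    """
    ref = _reference_with_element(5, seed=child_seed(seed, 51))
    s = ref.elements[0].start
    rng = np.random.default_rng(seed)
    carriers = rng.choice(n_clones, size=n_deleted, replace=False)
    deletions = [(int(i), (s - 20, s - 12)) for i in carriers]
    clone_set = synthetic.gen_clone_set(ref, n_clones=n_clones,
                                        deletions=deletions,
                                        cfg=synthetic.SimConfig(seed=seed))
    alns = [bisulfite.align_clone(ref, seq, clone_id=cid)
            for cid, seq in clone_set.clones]
    _, freq = bisulfite.call_deletions(alns, ref.elements[0], window=50,
                                       min_del_len=2)
    return 100.0 * freq


def deletion_pct_overlap_fixture(seed: int = 3, n_clones: int = 27) -> float:
    """Deletion percentage when every clone's deletion crosses the 5' boundary.

    Each clone of a d(TCCC)9 region carries a 10 bp deletion starting 6 bp
    5' of the element and extending 4 bp into it.
    """
    ref = _reference_with_element(9, seed=child_seed(seed, 52))
    s = ref.elements[0].start
    deletions = [(i, (s - 6, s + 4)) for i in range(n_clones)]
    clone_set = synthetic.gen_clone_set(ref, n_clones=n_clones,
                                        deletions=deletions,
                                        cfg=synthetic.SimConfig(seed=seed))
    alns = [bisulfite.align_clone(ref, seq, clone_id=cid)
            for cid, seq in clone_set.clones]
    _, freq = bisulfite.call_deletions(alns, ref.elements[0], window=50,
                                       min_del_len=2)
    return 100.0 * freq


def _species_table(seed: int, fragment_fraction: float = 0.0,
                   n_molecules: int = 5000) -> massdist.SpeciesTable:
    ref_mass = massdist.oligo_mass("TCCC" * 9)
    peaks = synthetic.gen_peak_list(
        ref_mass=ref_mass, n_cytosines=N_CYTOSINES_36MER,
        p_convert=DU_P_CONVERT, n_molecules=n_molecules,
        fragment_fraction=fragment_fraction,
        cfg=synthetic.SimConfig(seed=seed))
    return massdist.assign_du_counts(peaks, ref_mass=ref_mass,
                                     n_cytosines=N_CYTOSINES_36MER)


def mass_mode(seed: int = 11, n_molecules: int = 5000) -> int:
    """Modal dU count of a binomial synthetic peak list for the 36mer."""
    table = _species_table(seed, n_molecules=n_molecules)
    return massdist.distribution_stats(table).mode_k


def intact_pct(seed: int = 11, fragment_fraction: float = FRAGMENT_FRACTION,
               n_molecules: int = 5000) -> float:
    """Intact (at-or-above reference mass) percentage with fragment peaks."""
    table = _species_table(seed, fragment_fraction=fragment_fraction,
                           n_molecules=n_molecules)
    return 100.0 * table.intact_fraction


def run_reproduction_workflow(seed: int = 1) -> dict:
    """Run every reproduction stage and return one summary dict.

    All randomness derives from ``seed`` via per-stage child seeds, so the
    same seed gives an identical summary.
    """
    profile = published_length_profile()
    assoc = profile_association(profile, ph_threshold=7.0)
    summary = {
        "seed": seed,
        "ph_t_recovered_tccc9": recover_ph_t(PH_T_9, seed=child_seed(seed, 1)),
        "ph_t_recovered_tccc5": recover_ph_t(PH_T_5, seed=child_seed(seed, 2)),
        "tm_recovered_ph65_c": recover_tm(TM_9_PH65),
        "tm_recovered_ph53_c": recover_tm(TM_9_PH53),
        "conversion_pct_tccc9": recover_conversion_pct(
            seed=child_seed(seed, 7)),
        "deletion_pct_upstream": deletion_pct_upstream_fixture(
            seed=child_seed(seed, 3)),
        "deletion_pct_overlap": deletion_pct_overlap_fixture(
            seed=child_seed(seed, 3)),
        "du_mode": mass_mode(seed=child_seed(seed, 11)),
        "intact_pct": intact_pct(seed=child_seed(seed, 11)),
        "impairment_probability": impairment_probability(SUPPRESSION),
        "profile_spearman_rho": assoc.rho,
        "profile_threshold_consistency": assoc.threshold_consistency,
    }
    return summary
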