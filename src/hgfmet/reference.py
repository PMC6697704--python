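"""Reference HGF/Met–integrin pathway model.

Builds the 52-species, 69-parameter network: HGF binding and activation of
Met with and without the α5β1 co-receptor, integrin-dependent receptor
trafficking (free phospho-Met internalizes and degrades fast; the
integrin-bound receptor internalizes slowly and recycles efficiently), the
Gab1/PI3K/Akt and Grb2/SOS/Ras/Raf/MEK/ERK/RSK cascades with their
feedback loops (RSK→SOS negative, ERK→Raf positive, ERK→Gab1 negative,
ERK→PI3K positive crosstalk, PDK1→MEK crosstalk, Akt-side suppression of
Raf), and the four drug mechanisms plus the node-level inhibitors used for
calibration-style experiments.

The numeric tables bundled under ``data/`` are a synthetic reference
parameterization: protein abundances on the scale of hepatocyte proteomic
copy numbers, and rate constants calibrated by the package itself so that
published summary observables of this pathway hold (≈50% of Met
internalized at 15 min of HGF exposure, ≈73% of phospho-Met signaling from
endosomes at 120 min, sorafenib half-maximal on pERK near 200 nM).
56 of the 69 parameters are flagged free for calibration; ligand and drug
binding constants and the node-inhibitor strengths are fixed.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .network import Modifier, ParameterDef, PathwayModel, ReactionDef, SpeciesDef

__all__ = ["build_reference_model", "PMET_SPECIES", "COHORT_PROTEINS"]

#: All phospho-Met-containing species; each carries one active receptor.
PMET_SPECIES = ("pMet", "pMet_Itg", "pMet_i", "pMet_Itg_i")

#: Species carrying a Met receptor (for internalized-fraction bookkeeping).
MET_SURFACE = ("Met", "Met_Itg", "Met_HGF", "Met_Itg_HGF", "pMet", "pMet_Itg",
               "Met_Cabo", "Met_Itg_Cabo")
MET_INTERNAL = ("Met_i", "pMet_i", "pMet_Itg_i")

#: Proteins a virtual-cohort profile may scale, with the species (and
#: synthesis parameters) that carry their abundance.
COHORT_PROTEINS = {
    "Met": {"species": ["Met"], "synthesis": ["ksyn_Met"]},
    "Itg": {"species": ["Itg"], "synthesis": ["ksyn_Itg"]},
    "Gab1": {"species": ["Gab1"], "synthesis": []},
    "Grb2": {"species": ["Grb2"], "synthesis": []},
    "PI3K": {"species": ["PI3K"], "synthesis": []},
    "Akt": {"species": ["Akt"], "synthesis": []},
    "PDK1": {"species": ["PDK1"], "synthesis": []},
    "SOS": {"species": ["SOS"], "synthesis": []},
    "Ras": {"species": ["Ras"], "synthesis": []},
    "Raf": {"species": ["Raf"], "synthesis": []},
    "MEK": {"species": ["MEK"], "synthesis": []},
    "ERK": {"species": ["ERK"], "synthesis": []},
    "RSK": {"species": ["RSK"], "synthesis": []},
}

CONSERVED_PAIRS = {
    "Gab1": ("Gab1", "aGab1"),
    "Grb2": ("Grb2", "aGrb2"),
    "PI3K": ("PI3K", "aPI3K"),
    "PIP": ("PIP2", "PIP3"),
    "Akt": ("Akt", "pAkt"),
    "PDK1": ("PDK1", "aPDK1"),
    "SOS": ("SOS", "aSOS"),
    "Ras": ("Ras", "aRas"),
    "Raf": ("Raf", "aRaf"),
    "MEK": ("MEK", "pMEK"),
    "ERK": ("ERK", "pERK"),
    "RSK": ("RSK", "pRSK", "ppRSK"),
}

READOUTS = {
    "pAkt": {"pAkt": 1.0},
    "pERK": {"pERK": 1.0},
    "pMEK": {"pMEK": 1.0},
    "pRSK": {"pRSK": 1.0},
    "ppRSK": {"ppRSK": 1.0},
    "pMet_surface": {"pMet": 1.0, "pMet_Itg": 1.0},
    "pMet_internal": {"pMet_i": 1.0, "pMet_Itg_i": 1.0},
    "pMet_total": {s: 1.0 for s in PMET_SPECIES},
}


def _load_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    base = resources.files("hgfmet") / "data"
    sp = pd.read_csv(str(base / "reference_species.tsv"), sep="\t")
    pr = pd.read_csv(str(base / "reference_parameters.tsv"), sep="\t",
                     na_values=["."])
    return sp, pr


def build_reference_model() -> PathwayModel:
    """Build the reference pathway model from the bundled definition tables."""
    sp_tab, pr_tab = _load_tables()
    species = [
        SpeciesDef(r["name"], r["compartment"], r["role"],
                   float(r["initial_amount"]), bool(int(r["constant"])))
        for _, r in sp_tab.iterrows()
    ]
    parameters = []
    for _, r in pr_tab.iterrows():
        free = bool(int(r["free"]))
        bounds = (float(r["lower"]), float(r["upper"])) if free else None
        parameters.append(ParameterDef(r["name"], float(r["value"]), free, bounds))

    ab = dict(zip(sp_tab["name"], sp_tab["initial_amount"].astype(float)))
    akt_t = ab["Akt"]
    erk_t = ab["ERK"]
    rsk_t = ab["RSK"]
    pdk1_t = ab["PDK1"]
    pip_t = ab["PIP2"]
    ptp0 = ab["PTP"]
    pp2a0 = ab["PP2A"]

    def m(kind, species, **kw):
        return Modifier(kind, species, **kw)

    block_Met = m("block", "Meti", weight_param="s_Met")
    block_PDK1 = m("block", "PDK1i", weight_param="s_PDK1")
    block_MEK = m("block", "MEKi", weight_param="s_MEK")
    block_PI3K = m("block", "PI3Ki", weight_param="s_PI3K")
    block_ERK = m("block", "ERKi", weight_param="s_ERK")
    block_sor = m("block", "Sorafenib", weight_param="s_sor", k_param="K_sor")

    R: list[ReactionDef] = []

    def rxn(name, reactants, products, k, mods=()):
        R.append(ReactionDef(name, tuple(reactants), tuple(products), k, tuple(mods)))

    # ligand binding and receptor activation (activation rate independent of
    # integrin association: kact_Met shared)
    rxn("hgf_binds_met", [("Met", 1), ("HGF", 1)], [("Met_HGF", 1)], "kon_HGF_Met")
    rxn("hgf_unbinds_met", [("Met_HGF", 1)], [("Met", 1), ("HGF", 1)], "koff_HGF_Met")
    rxn("hgf_binds_metitg", [("Met_Itg", 1), ("HGF", 1)], [("Met_Itg_HGF", 1)], "kon_HGF_Met")
    rxn("hgf_unbinds_metitg", [("Met_Itg_HGF", 1)], [("Met_Itg", 1), ("HGF", 1)], "koff_HGF_Met")
    rxn("met_binds_itg", [("Met", 1), ("Itg", 1)], [("Met_Itg", 1)], "kon_Met_Itg")
    rxn("met_unbinds_itg", [("Met_Itg", 1)], [("Met", 1), ("Itg", 1)], "koff_Met_Itg")
    rxn("methgf_binds_itg", [("Met_HGF", 1), ("Itg", 1)], [("Met_Itg_HGF", 1)], "kon_Met_Itg")
    rxn("methgf_unbinds_itg", [("Met_Itg_HGF", 1)], [("Met_HGF", 1), ("Itg", 1)], "koff_Met_Itg")
    rxn("met_activation", [("Met_HGF", 1)], [("pMet", 1)], "kact_Met")
    rxn("metitg_activation", [("Met_Itg_HGF", 1)], [("pMet_Itg", 1)], "kact_Met")
    rxn("met_basal_activation", [("Met", 1)], [("pMet", 1)], "kbasal_act_Met")
    rxn("metitg_basal_activation", [("Met_Itg", 1)], [("pMet_Itg", 1)], "kbasal_act_Met")
    rxn("pmet_dephos_surface", [("pMet", 1)], [("Met_HGF", 1)], "kdephos_pMet_surf",
        [m("scaled", "PTP", scale=ptp0)])
    rxn("pmetitg_dephos_surface", [("pMet_Itg", 1)], [("Met_Itg_HGF", 1)], "kdephos_pMet_surf",
        [m("scaled", "PTP", scale=ptp0)])

    # trafficking: constitutive rates are integrin-independent; the
    # phospho-receptor trafficking is integrin-modulated
    rxn("met_internalization", [("Met", 1)], [("Met_i", 1)], "kint_Met")
    rxn("metitg_internalization", [("Met_Itg", 1)], [("Met_i", 1), ("Itg_i", 1)], "kint_Met")
    # ligand-induced endocytosis: occupied receptors internalize at the
    # induced rates whether or not they have autophosphorylated yet
    rxn("methgf_internalization", [("Met_HGF", 1)], [("Met_i", 1)], "kint_pMet")
    rxn("metitghgf_internalization", [("Met_Itg_HGF", 1)], [("Met_i", 1), ("Itg_i", 1)], "kint_pMetItg")
    rxn("pmet_internalization", [("pMet", 1)], [("pMet_i", 1)], "kint_pMet")
    rxn("pmetitg_internalization", [("pMet_Itg", 1)], [("pMet_Itg_i", 1)], "kint_pMetItg")
    rxn("met_recycling", [("Met_i", 1)], [("Met", 1)], "krec_Met")
    rxn("pmet_recycling", [("pMet_i", 1)], [("pMet", 1)], "krec_pMet")
    rxn("pmetitg_recycling", [("pMet_Itg_i", 1)], [("pMet_Itg", 1)], "krec_pMetItg")
    rxn("pmet_dephos_endosome", [("pMet_i", 1)], [("Met_i", 1)], "kdephos_pMet_i",
        [m("scaled", "PTP", scale=ptp0)])
    rxn("pmetitg_dephos_endosome", [("pMet_Itg_i", 1)], [("Met_i", 1), ("Itg_i", 1)],
        "kdephos_pMet_i", [m("scaled", "PTP", scale=ptp0)])
    rxn("met_i_degradation", [("Met_i", 1)], [], "kdeg_Met_i")
    rxn("pmet_i_degradation", [("pMet_i", 1)], [], "kdeg_pMet_i")
    rxn("pmetitg_i_degradation", [("pMet_Itg_i", 1)], [], "kdeg_pMetItg_i")
    rxn("met_synthesis", [], [("Met", 1)], "ksyn_Met")
    rxn("met_surface_degradation", [("Met", 1)], [], "kdeg_Met")
    rxn("metitg_surface_degradation", [("Met_Itg", 1)], [("Itg", 1)], "kdeg_Met")
    rxn("itg_synthesis", [], [("Itg", 1)], "ksyn_Itg")
    rxn("itg_degradation", [("Itg", 1)], [], "kdeg_Itg")
    rxn("itg_internalization", [("Itg", 1)], [("Itg_i", 1)], "kint_Itg")
    rxn("itg_recycling", [("Itg_i", 1)], [("Itg", 1)], "krec_Itg")
    rxn("itg_i_degradation", [("Itg_i", 1)], [], "kdeg_Itg_i")

    # adapter layer: driven by the total phospho-Met pool (surface and
    # endosomal receptors signal alike); Met-node inhibitor throttles the
    # receptor output, ERK feedback desensitizes Gab1
    rxn("gab1_activation", [("Gab1", 1)], [("aGab1", 1)], "kact_Gab1",
        [m("mass", PMET_SPECIES), block_Met,
         m("inhibit", "pERK", weight_param="kfb_ERK_Gab1", scale=erk_t)])
    rxn("gab1_deactivation", [("aGab1", 1)], [("Gab1", 1)], "kdeact_Gab1")
    rxn("grb2_activation", [("Grb2", 1)], [("aGrb2", 1)], "kact_Grb2",
        [m("mass", PMET_SPECIES), block_Met])
    rxn("grb2_deactivation", [("aGrb2", 1)], [("Grb2", 1)], "kdeact_Grb2")

    # PI3K/Akt arm
    rxn("pi3k_activation", [("PI3K", 1)], [("aPI3K", 1)], "kact_PI3K",
        [m("mass", "aGab1")])
    rxn("pi3k_activation_by_perk", [("PI3K", 1)], [("aPI3K", 1)], "kact_PI3K_pERK",
        [m("mass", "pERK")])
    rxn("pi3k_deactivation", [("aPI3K", 1)], [("PI3K", 1)], "kdeact_PI3K")
    rxn("pip3_production", [("PIP2", 1)], [("PIP3", 1)], "kcat_PIP3",
        [m("mass", "aPI3K"), block_PI3K])
    rxn("pip3_turnover", [("PIP3", 1)], [("PIP2", 1)], "kdeg_PIP3")
    rxn("akt_activation", [("Akt", 1)], [("pAkt", 1)], "kact_Akt",
        [m("scaled", "PIP3", scale=pip_t), m("scaled", "aPDK1", scale=pdk1_t),
         block_PDK1])
    rxn("akt_deactivation", [("pAkt", 1)], [("Akt", 1)], "kdeact_Akt",
        [m("scaled", "PP2A", scale=pp2a0)])
    rxn("pdk1_activation", [("PDK1", 1)], [("aPDK1", 1)], "kact_PDK1",
        [m("scaled", "PIP3", scale=pip_t)])
    rxn("pdk1_deactivation", [("aPDK1", 1)], [("PDK1", 1)], "kdeact_PDK1")

    # Ras/ERK arm with RSK negative feedback on SOS, ERK positive feedback
    # on Raf, and Akt-side suppression of Raf
    rxn("sos_activation", [("SOS", 1)], [("aSOS", 1)], "kact_SOS",
        [m("mass", "aGrb2"),
         m("inhibit", ("pRSK", "ppRSK"), weight_param="kfb_RSK_SOS", scale=rsk_t)])
    rxn("sos_deactivation", [("aSOS", 1)], [("SOS", 1)], "kdeact_SOS")
    rxn("ras_activation", [("Ras", 1)], [("aRas", 1)], "kact_Ras",
        [m("mass", "aSOS")])
    rxn("ras_deactivation", [("aRas", 1)], [("Ras", 1)], "kdeact_Ras")
    rxn("raf_activation", [("Raf", 1)], [("aRaf", 1)], "kact_Raf",
        [m("mass", "aRas"),
         m("activate", "pERK", weight_param="kfb_ERK_Raf", scale=erk_t),
         m("inhibit", "pAkt", weight_param="kfb_Akt_Raf", scale=akt_t)])
    rxn("raf_deactivation", [("aRaf", 1)], [("Raf", 1)], "kdeact_Raf")
    rxn("mek_activation", [("MEK", 1)], [("pMEK", 1)], "kact_MEK",
        [m("mass", "aRaf"), block_sor])
    rxn("mek_activation_by_pdk1", [("MEK", 1)], [("pMEK", 1)], "kact_MEK_PDK1",
        [m("scaled", "aPDK1", scale=pdk1_t), block_PDK1])
    rxn("mek_deactivation", [("pMEK", 1)], [("MEK", 1)], "kdeact_MEK",
        [m("scaled", "PP2A", scale=pp2a0)])
    rxn("erk_activation", [("ERK", 1)], [("pERK", 1)], "kact_ERK",
        [m("mass", "pMEK"), block_MEK, block_ERK])
    rxn("erk_deactivation", [("pERK", 1)], [("ERK", 1)], "kdeact_ERK")
    rxn("rsk_activation", [("RSK", 1)], [("pRSK", 1)], "kact_RSK",
        [m("mass", "pERK")])
    rxn("rsk_second_phosphorylation", [("pRSK", 1)], [("ppRSK", 1)], "kact_RSK_PDK1",
        [m("scaled", "aPDK1", scale=pdk1_t), block_PDK1])
    rxn("rsk_deactivation", [("pRSK", 1)], [("RSK", 1)], "kdeact_RSK")
    rxn("pprsk_deactivation", [("ppRSK", 1)], [("pRSK", 1)], "kdeact_ppRSK")

    # AXT050: binds free integrin and strips it from Met-containing complexes
    rxn("axt_binds_itg", [("Itg", 1), ("AXT050", 1)], [("AXT_Itg", 1)], "kon_AXT")
    rxn("axt_unbinds_itg", [("AXT_Itg", 1)], [("Itg", 1), ("AXT050", 1)], "koff_AXT")
    rxn("axt_strips_metitg", [("Met_Itg", 1), ("AXT050", 1)],
        [("Met", 1), ("AXT_Itg", 1)], "kstrip_AXT")
    rxn("axt_strips_metitghgf", [("Met_Itg_HGF", 1), ("AXT050", 1)],
        [("Met_HGF", 1), ("AXT_Itg", 1)], "kstrip_AXT")
    rxn("axt_strips_pmetitg", [("pMet_Itg", 1), ("AXT050", 1)],
        [("pMet", 1), ("AXT_Itg", 1)], "kstrip_AXT")
    rxn("axtitg_turnover", [("AXT_Itg", 1)], [], "kdeg_Itg")

    # cabozantinib: occupies Met so HGF cannot activate it; bound receptor
    # follows constitutive trafficking
    rxn("cabo_binds_met", [("Met", 1), ("Cabozantinib", 1)], [("Met_Cabo", 1)], "kon_Cabo")
    rxn("cabo_unbinds_met", [("Met_Cabo", 1)], [("Met", 1), ("Cabozantinib", 1)], "koff_Cabo")
    rxn("cabo_binds_metitg", [("Met_Itg", 1), ("Cabozantinib", 1)], [("Met_Itg_Cabo", 1)], "kon_Cabo")
    rxn("cabo_unbinds_metitg", [("Met_Itg_Cabo", 1)], [("Met_Itg", 1), ("Cabozantinib", 1)], "koff_Cabo")
    rxn("metcabo_internalization", [("Met_Cabo", 1)], [("Met_i", 1)], "kint_Met")
    rxn("metitgcabo_internalization", [("Met_Itg_Cabo", 1)], [("Met_i", 1), ("Itg_i", 1)], "kint_Met")
    rxn("metcabo_degradation", [("Met_Cabo", 1)], [], "kdeg_Met")
    rxn("metitgcabo_degradation", [("Met_Itg_Cabo", 1)], [("Itg", 1)], "kdeg_Met")

    model = PathwayModel(species, parameters, R,
                         conservation_groups=dict(CONSERVED_PAIRS),
                         readouts=dict(READOUTS),
                         name="hgf_met_alpha5beta1")
    return model


def met_internalized_fraction(model: PathwayModel, state: np.ndarray) -> float:
    """Fraction of the (undegraded) Met receptor pool in endosomes."""
    surf = sum(state[model.species_index[s]] for s in MET_SURFACE)
    intern = sum(state[model.species_index[s]] for s in MET_INTERNAL)
    return float(intern / (surf + intern))


def pmet_internal_share(model: PathwayModel, state: np.ndarray) -> float:
    """Share of total phospho-Met that is in the internalized pool."""
    intern = state[model.species_index["pMet_i"]] + state[model.species_index["pMet_Itg_i"]]
    total = sum(state[model.species_index[s]] for s in PMET_SPECIES)
    return float(intern / total)
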