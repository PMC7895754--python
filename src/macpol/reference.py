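"""Curated reduced seven-pathway macrophage polarization network.

Encodes the qualitative topology and directional regulation of the M1-M2
signaling network — six receptor-mediated cytokine pathways (IFNG, TNFA,
IL1B, IL4, IL10, VEGF) plus an oxygen-sensing pathway (HYPOXIA) — with a
nominal parameterization calibrated at the desk to reproduce the documented
stimulus->target response directions and plausible time scales (receptor
events: minutes; transcription factors: 0.5-4 h; markers: 4-48 h).

Conventions
-----------
* catalysis: the catalyst appears with stoichiometry 1 on both sides;
* induction: zeroth-order Hill-activated synthesis of the target;
* repression: catalytic first-order removal of the target by the repressor;
* reversible steps: paired irreversible reactions (kf*/kr*).

Named parameters targeted by the shipped intervention screen:
``kf3``  STAT1 phosphorylation by active JAK,
``k26``  STAT6 dephosphorylation,
``k127`` STAT3 dephosphorylation,
``k85``  IRF1 degradation,
``k101`` SOCS1 degradation,
``kf62`` PHD-mediated HIF hydroxylation (oxygen-scaled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

from .errors import ConfigurationError
from .io import ModelDocument
from .network import Network, Parameter, RateLaw, Reaction, Species

PATHWAY_MODULES = ("IFNG", "TNFA", "IL1B", "IL4", "IL10", "VEGF", "HYPOXIA")

# Hill-function shape constants shared across transcriptional targets
KH, NH = 2000.0, 1.5        # hub transcription factors (active forms)
KHIF, NHIF = 2500.0, 2.0    # HIF1A / HIF2A
KIRF1, NIRF1 = 1500.0, 1.5  # IRF1
KIRF9, NIRF9 = 12000.0, 3.0  # IRF9
KNF = 6000.0                # nuclear NF-kB (sits above the autocrine tone)


@dataclass
class PathwayModule:
    name: str
    species_ids: List[str]
    reaction_ids: List[str]


class _Builder:
    def __init__(self):
        self.species: List[Species] = []
        self.reactions: List[Reaction] = []
        self.parameters: List[Parameter] = []
        self._sids = set()
        self._pids = set()

    def sp(self, sid, role, comp, init, constant=False, secreted=False, name=""):
        if sid in self._sids:
            raise ConfigurationError(f"duplicate species {sid}")
        self._sids.add(sid)
        self.species.append(
            Species(sid, name or sid, role, comp, init, constant, secreted)
        )

    def par(self, pid, value, desc=""):
        if pid not in self._pids:
            self._pids.add(pid)
            self.parameters.append(Parameter(pid, value, desc))
        return pid

    def rxn(self, rid, module, law, reactants=(), products=(), tags=()):
        self.reactions.append(
            Reaction(
                id=rid,
                reactants=[(s, 1.0) if isinstance(s, str) else s for s in reactants],
                products=[(s, 1.0) if isinstance(s, str) else s for s in products],
                law=law,
                tags=list(tags),
                module=module,
            )
        )

    # -- idioms ----------------------------------------------------------
    def ma(self, rid, module, kval, reactants, products, tags=(), pid=None):
        p = self.par(pid or f"k_{rid}", kval)
        self.rxn(rid, module, RateLaw("mass_action", rate_param=p),
                 reactants, products, tags)

    def cat(self, rid, module, kval, substrate, product, catalyst, tags=(), pid=None):
        """substrate + catalyst -> product + catalyst (activation/conversion)."""
        p = self.par(pid or f"k_{rid}", kval)
        self.rxn(rid, module, RateLaw("mass_action", rate_param=p),
                 [substrate, catalyst], [product, catalyst], tags)

    def deg_by(self, rid, module, kval, target, catalyst, tags=(), pid=None):
        """target + catalyst -> catalyst (catalytic removal = repression)."""
        p = self.par(pid or f"k_{rid}", kval)
        self.rxn(rid, module, RateLaw("mass_action", rate_param=p),
                 [target, catalyst], [catalyst], tags)

    def fo(self, rid, module, kval, substrate, products=(), tags=(), pid=None):
        p = self.par(pid or f"k_{rid}", kval)
        self.rxn(rid, module, RateLaw("first_order_decay", rate_param=p),
                 [substrate], products, tags)

    def syn(self, rid, module, kval, product, tags=(), pid=None):
        p = self.par(pid or f"k_{rid}", kval)
        self.rxn(rid, module, RateLaw("synthesis", rate_param=p),
                 [], [product], tags)

    def hill(self, rid, module, vmax, regulator, product, K=KH, n=NH,
             tags=(), pid=None, inhibit=False):
        p = self.par(pid or f"k_{rid}", vmax)
        kind = "hill_inhibition" if inhibit else "hill_activation"
        self.rxn(rid, module, RateLaw(kind, rate_param=p, K=K, n=n,
                                      regulator=regulator),
                 [], [product], tags)

    def receptor_module(self, lig, module, *, ks_r=500.0, kd_r=0.05,
                        kf=3e-6, kr=0.1, kact=6.0, kdeact=1.0,
                        kint=0.5, krec=0.3, kideg=0.05, kd_l=0.05,
                        r0=1e4):
        """Ligand binding, receptor activation, internalization, recycling,
        degradation, plus basal receptor turnover and ligand clearance."""
        L, R, C, CA, RI = (f"{lig}_ext", f"R_{lig}", f"C_{lig}",
                           f"CA_{lig}", f"RI_{lig}")
        self.sp(L, "ligand", "extracellular", 0.0, secreted=True)
        self.sp(R, "receptor", "cytoplasm", r0)
        self.sp(C, "complex", "cytoplasm", 0.0)
        self.sp(CA, "complex", "cytoplasm", 0.0)
        self.sp(RI, "receptor", "cytoplasm", 0.0)
        lo = lig.lower()
        self.syn(f"{lo}_r_syn", module, ks_r, R, tags=("translation",))
        self.fo(f"{lo}_r_deg", module, kd_r, R)
        self.ma(f"{lo}_bind", module, kf, [L, R], [C], pid=f"kf_{lo}_bind")
        self.fo(f"{lo}_unbind", module, kr, C, [L, R], pid=f"kr_{lo}_bind")
        self.fo(f"{lo}_c_act", module, kact, C, [CA])
        self.fo(f"{lo}_c_deact", module, kdeact, CA, [C])
        self.fo(f"{lo}_internalize", module, kint, CA, [RI])
        self.fo(f"{lo}_recycle", module, krec, RI, [R])
        self.fo(f"{lo}_ri_deg", module, kideg, RI)
        self.fo(f"{lo}_l_clear", module, kd_l, L)
        return CA

    def hub(self, inact, act, module, pool, *, basal=None, kdeact=2.0,
            kdeact_pid=None):
        """Inactive/active pair with optional basal activation and deactivation."""
        self.sp(inact, "protein", "cytoplasm", pool)
        self.sp(act, "phospho-protein", "cytoplasm", 0.0)
        lo = inact.lower()
        if basal:
            self.fo(f"{lo}_basal_act", module, basal, inact, [act])
        self.fo(f"{lo}_deact", module, kdeact, act, [inact], pid=kdeact_pid)

    def marker(self, name, module, *, transcription, repressors=(),
               mrna_decay, ktl=2.0, kp_decay, ksec=None, ext_decay=0.05,
               mrna0=20.0, prot0=100.0):
        """Transcription + translation (+ secretion) marker cassette.

        ``transcription``: list of (regulator, Vmax, K, n) Hill activations
        plus a leading basal rate; ``repressors``: (species, k) catalytic
        mRNA removal.
        """
        lo = name.lower()
        m, prot, ext = f"{name}_m", name, f"{name}_ext"
        self.sp(m, "mRNA", "cytoplasm", mrna0)
        self.sp(prot, "protein", "cytoplasm", prot0)
        basal, hills = transcription[0], transcription[1:]
        self.syn(f"{lo}_tx_basal", module, basal, m, tags=("transcription",))
        for i, (reg, v, K, n) in enumerate(hills):
            self.hill(f"{lo}_tx_{reg.lower()}", module, v, reg, m, K=K, n=n,
                      tags=("transcription",))
        for reg, k in repressors:
            self.deg_by(f"{lo}_mrep_{reg.lower()}", module, k, m, reg)
        self.fo(f"{lo}_m_deg", module, mrna_decay, m)
        self.cat(f"{lo}_tl", module, ktl, m, prot, m, tags=("translation",))
        # translation keeps the mRNA: encode as mRNA -> mRNA + protein
        self.reactions[-1].reactants = [(m, 1.0)]
        self.reactions[-1].products = [(m, 1.0), (prot, 1.0)]
        self.fo(f"{lo}_p_deg", module, kp_decay, prot)
        if ksec is not None:
            if ext not in self._sids:
                self.sp(ext, "ligand", "extracellular", 0.0, secreted=True)
            self.fo(f"{lo}_secrete", module, ksec, prot, [ext],
                    tags=("secretion",))
            if f"{lo}_ext_clear" not in {r.id for r in self.reactions}:
                self.fo(f"{lo}_ext_clear", module, ext_decay, ext)


def build_reference_network(config: Optional[dict] = None) -> ModelDocument:
    """Construct the reference network and its nominal parameterization.

    ``config`` may carry ``parameter_overrides`` (id -> value) and
    ``marker_panel`` (replacing the default panel annotation).
    """
    b = _Builder()

    # ---------------- receptor modules (6 ligand pathways) --------------
    ca_ifng = b.receptor_module("IFNG", "IFNG")
    ca_tnfa = b.receptor_module("TNFA", "TNFA")
    ca_il1b = b.receptor_module("IL1B", "IL1B")
    ca_il4 = b.receptor_module("IL4", "IL4", kf=1e-6)
    ca_il10 = b.receptor_module("IL10", "IL10")
    ca_vegf = b.receptor_module("VEGFA", "VEGF")
    # IL-10 upregulates IL-4 receptor production
    b.hill("il4_r_syn_stat3", "IL10", 400.0, "STAT3p", "R_IL4",
           tags=("translation",))

    # VEGF165b: non-signaling isoform competing for the same receptor
    b.sp("VEGFB_ext", "ligand", "extracellular", 2000.0)
    b.sp("C_VEGFB", "complex", "cytoplasm", 0.0)
    b.syn("vegfb_supply", "VEGF", 100.0, "VEGFB_ext")
    b.fo("vegfb_clear", "VEGF", 0.05, "VEGFB_ext")
    b.ma("vegfb_bind", "VEGF", 3e-6, ["VEGFB_ext", "R_VEGFA"], ["C_VEGFB"],
         pid="kf_vegfb_bind")
    b.fo("vegfb_unbind", "VEGF", 0.1, "C_VEGFB", ["VEGFB_ext", "R_VEGFA"],
         pid="kr_vegfb_bind")
    b.fo("vegfb_internalize", "VEGF", 0.5, "C_VEGFB", ["RI_VEGFA"])

    # ---------------- signaling hubs ------------------------------------
    b.hub("JAK", "JAKa", "IFNG", 1e4, basal=0.001, kdeact=2.0)
    b.cat("jak_act", "IFNG", 1e-3, "JAK", "JAKa", ca_ifng)

    # STAT1 pool has explicit turnover so miR-146b can deplete it
    b.sp("STAT1", "protein", "cytoplasm", 1e4)
    b.sp("STAT1p", "phospho-protein", "cytoplasm", 0.0)
    b.syn("stat1_syn", "IFNG", 100.0, "STAT1", tags=("translation",))
    b.fo("stat1_deg", "IFNG", 0.01, "STAT1")
    b.fo("stat1p_deg", "IFNG", 0.01, "STAT1p")
    b.fo("stat1_basal_act", "IFNG", 0.0005, "STAT1", ["STAT1p"])
    b.cat("stat1_act", "IFNG", 1e-3, "STAT1", "STAT1p", "JAKa", pid="kf3")
    b.fo("stat1_dephos", "IFNG", 2.0, "STAT1p", ["STAT1"])

    b.hub("STAT3", "STAT3p", "IL10", 1e4, basal=0.002, kdeact=2.0,
          kdeact_pid="k127")
    b.cat("stat3_act_il10", "IL10", 1e-3, "STAT3", "STAT3p", ca_il10)
    b.cat("stat3_act_ifng", "IFNG", 8e-5, "STAT3", "STAT3p", ca_ifng)
    b.cat("stat3_act_vegf", "VEGF", 9e-4, "STAT3", "STAT3p", ca_vegf)

    b.hub("STAT6", "STAT6p", "IL4", 1e4, basal=0.012, kdeact=2.0,
          kdeact_pid="k26")
    b.cat("stat6_act", "IL4", 1e-3, "STAT6", "STAT6p", ca_il4)

    b.hub("AKT", "AKTa", "VEGF", 1e4, basal=0.002, kdeact=2.0)
    for src, cat_sp in (("il1b", "TRAF6a"), ("il10", ca_il10),
                        ("il4", ca_il4), ("vegf", ca_vegf)):
        b.cat(f"akt_act_{src}", "VEGF", 5e-4, "AKT", "AKTa", cat_sp)

    b.hub("ERK", "ERKa", "TNFA", 1e4, basal=0.002, kdeact=2.0)
    for src, cat_sp in (("traf6", "TRAF6a"), ("rip1", "RIP1a"),
                        ("il10", ca_il10), ("il4", ca_il4), ("vegf", ca_vegf)):
        b.cat(f"erk_act_{src}", "TNFA", 5e-4, "ERK", "ERKa", cat_sp)
    b.hub("P38", "P38a", "TNFA", 1e4, basal=0.002, kdeact=2.0)
    b.cat("p38_act_traf6", "IL1B", 5e-4, "P38", "P38a", "TRAF6a")
    b.cat("p38_act_rip1", "TNFA", 5e-4, "P38", "P38a", "RIP1a")
    b.hub("JNK", "JNKa", "TNFA", 1e4, basal=0.002, kdeact=2.0)
    b.cat("jnk_act_traf6", "IL1B", 5e-4, "JNK", "JNKa", "TRAF6a")
    b.cat("jnk_act_rip1", "TNFA", 5e-4, "JNK", "JNKa", "RIP1a")

    # IL-1B axis: IRAK (miR-93 target) -> TRAF6 -> IKK
    b.sp("IRAK", "protein", "cytoplasm", 6000.0)
    b.sp("IRAKa", "phospho-protein", "cytoplasm", 0.0)
    b.syn("irak_syn", "IL1B", 500.0, "IRAK", tags=("translation",))
    b.fo("irak_deg", "IL1B", 0.05, "IRAK")
    b.fo("iraka_deg", "IL1B", 0.05, "IRAKa")
    b.fo("irak_basal_act", "IL1B", 0.0005, "IRAK", ["IRAKa"])
    b.cat("irak_act", "IL1B", 9e-4, "IRAK", "IRAKa", ca_il1b)
    b.fo("irak_deact", "IL1B", 2.0, "IRAKa", ["IRAK"])
    b.hub("TRAF6", "TRAF6a", "IL1B", 1e4, kdeact=2.0)
    b.cat("traf6_act", "IL1B", 1.5e-4, "TRAF6", "TRAF6a", "IRAKa")

    # TNFA axis: RIP1
    b.hub("RIP1", "RIP1a", "TNFA", 1e4, basal=0.001, kdeact=2.0)
    b.cat("rip1_act", "TNFA", 1e-3, "RIP1", "RIP1a", ca_tnfa)

    # IKK / IkB / NF-kB core; IKK expression is hypoxia-enhanced
    b.sp("IKK", "protein", "cytoplasm", 11000.0)
    b.sp("IKKa", "phospho-protein", "cytoplasm", 50.0)
    b.sp("IKB", "protein", "cytoplasm", 2000.0)
    b.sp("NFKB", "protein", "cytoplasm", 1e4)
    b.sp("NFKBn", "protein", "nucleus", 60.0)
    b.syn("ikk_syn", "TNFA", 500.0, "IKK", tags=("translation",))
    b.hill("ikk_syn_hif1a", "HYPOXIA", 550.0, "HIF1A", "IKK", K=KHIF, n=NHIF,
           tags=("translation",))
    b.fo("ikk_deg", "TNFA", 0.05, "IKK")
    b.fo("ikka_deg", "TNFA", 0.05, "IKKa")
    b.fo("ikk_basal_act", "TNFA", 0.001, "IKK", ["IKKa"])
    b.cat("ikk_act_traf6", "IL1B", 2.2e-4, "IKK", "IKKa", "TRAF6a")
    b.cat("ikk_act_rip1", "TNFA", 3e-4, "IKK", "IKKa", "RIP1a")
    b.cat("ikk_act_ifng", "IFNG", 2e-4, "IKK", "IKKa", ca_ifng)
    b.fo("ikka_off", "TNFA", 1.0, "IKKa", ["IKK"])
    b.cat("ikka_off_a20", "TNFA", 6e-4, "IKKa", "IKK", "A20")
    b.syn("ikb_syn_basal", "TNFA", 300.0, "IKB", tags=("translation",))
    b.hill("ikb_syn_nfkb", "TNFA", 2000.0, "NFKBn", "IKB", K=3000.0, n=2.0,
           tags=("translation",))
    b.fo("ikb_deg", "TNFA", 0.1, "IKB")
    b.deg_by("ikb_deg_ikka", "TNFA", 5e-4, "IKB", "IKKa")
    b.cat("nfkb_in", "TNFA", 5e-4, "NFKB", "NFKBn", "IKKa")
    b.cat("nfkb_out", "TNFA", 2e-3, "NFKBn", "NFKB", "IKB")

    # ---------------- feedback regulators & miRNAs ----------------------
    b.sp("A20", "protein", "cytoplasm", 50.0)
    b.syn("a20_syn_basal", "TNFA", 10.0, "A20", tags=("translation",))
    b.hill("a20_syn_nfkb", "TNFA", 800.0, "NFKBn", "A20", K=KNF)
    b.fo("a20_deg", "TNFA", 0.2, "A20")

    b.sp("SOCS1", "protein", "cytoplasm", 150.0)
    b.syn("socs1_syn_basal", "IFNG", 30.0, "SOCS1", tags=("translation",))
    b.hill("socs1_syn_stat1", "IFNG", 400.0, "STAT1p", "SOCS1")
    b.hill("socs1_syn_stat6", "IL4", 200.0, "STAT6p", "SOCS1")
    b.hill("socs1_syn_nfkb", "IL1B", 100.0, "NFKBn", "SOCS1", K=KNF)
    b.fo("socs1_deg", "IFNG", 0.2, "SOCS1", pid="k101")
    b.deg_by("socs1_deg_mir155", "IL1B", 2e-5, "SOCS1", "MIR155")
    b.cat("stat3_off_socs1", "IL10", 5e-3, "STAT3p", "STAT3", "SOCS1")
    b.cat("jak_off_socs1", "IFNG", 5e-3, "JAKa", "JAK", "SOCS1")

    b.sp("SOCS3", "protein", "cytoplasm", 60.0)
    b.syn("socs3_syn_basal", "IL10", 10.0, "SOCS3", tags=("translation",))
    b.hill("socs3_syn_nfkb", "IL1B", 400.0, "NFKBn", "SOCS3", K=KNF)
    b.hill("socs3_syn_stat3", "IL10", 400.0, "STAT3p", "SOCS3")
    b.hill("socs3_syn_stat6", "IL4", 100.0, "STAT6p", "SOCS3")
    b.fo("socs3_deg", "IL10", 0.2, "SOCS3")

    b.sp("MIR155", "miRNA", "cytoplasm", 40.0)
    b.syn("mir155_syn_basal", "IL1B", 2.0, "MIR155", tags=("transcription",))
    b.hill("mir155_syn_nfkb", "IL1B", 400.0, "NFKBn", "MIR155", K=KNF,
           tags=("transcription",))
    b.fo("mir155_deg", "IL1B", 0.1, "MIR155")
    b.deg_by("mir155_rep_stat3", "IL10", 5e-4, "MIR155", "STAT3p")

    b.sp("MIR93", "miRNA", "cytoplasm", 1000.0)
    b.syn("mir93_syn", "HYPOXIA", 60.0, "MIR93", tags=("transcription",),
          pid="k_mir93_syn")
    b.fo("mir93_deg", "HYPOXIA", 0.06, "MIR93")
    b.deg_by("mir93_rep_nfkb", "HYPOXIA", 3e-5, "MIR93", "NFKBn")
    b.deg_by("mir93_rep_hif1a", "HYPOXIA", 5e-5, "MIR93", "HIF1A")
    b.deg_by("irak_rep_mir93", "HYPOXIA", 3e-5, "IRAK", "MIR93")
    b.deg_by("irf9_rep_mir93", "HYPOXIA", 8e-5, "IRF9", "MIR93")

    b.sp("MIR146B", "miRNA", "cytoplasm", 25.0)
    b.syn("mir146b_syn_basal", "IL10", 2.0, "MIR146B", tags=("transcription",))
    b.hill("mir146b_syn_stat3", "IL10", 300.0, "STAT3p", "MIR146B",
           tags=("transcription",))
    b.fo("mir146b_deg", "IL10", 0.1, "MIR146B")
    b.deg_by("stat1_rep_mir146b", "IL10", 2e-5, "STAT1", "MIR146B")

    # ---------------- transcription factors -----------------------------
    b.sp("IRF1", "protein", "nucleus", 100.0)
    b.syn("irf1_syn_basal", "IFNG", 60.0, "IRF1", tags=("translation",))
    b.hill("irf1_syn_stat1", "IFNG", 3000.0, "STAT1p", "IRF1")
    b.hill("irf1_syn_hif1a", "HYPOXIA", 330.0, "HIF1A", "IRF1", K=KHIF, n=NHIF)
    b.fo("irf1_deg", "IFNG", 1.0, "IRF1", pid="k85")
    b.deg_by("irf1_rep_irf4", "IL4", 1.6e-3, "IRF1", "IRF4")

    b.sp("IRF9", "protein", "nucleus", 5000.0)
    b.syn("irf9_syn", "HYPOXIA", 500.0, "IRF9", tags=("translation",))
    b.fo("irf9_deg", "HYPOXIA", 0.02, "IRF9")

    b.sp("IRF4", "protein", "nucleus", 50.0)
    b.syn("irf4_syn_basal", "IL4", 10.0, "IRF4", tags=("translation",))
    b.hill("irf4_syn_stat6", "IL4", 400.0, "STAT6p", "IRF4")
    b.fo("irf4_deg", "IL4", 0.2, "IRF4")
    b.sp("EGR2", "protein", "nucleus", 50.0)
    b.syn("egr2_syn_basal", "IL4", 10.0, "EGR2", tags=("translation",))
    b.hill("egr2_syn_stat6", "IL4", 300.0, "STAT6p", "EGR2")
    b.fo("egr2_deg", "IL4", 0.2, "EGR2")
    b.sp("PPARG", "protein", "nucleus", 100.0)
    b.syn("pparg_syn_basal", "IL4", 20.0, "PPARG", tags=("translation",))
    b.hill("pparg_syn_stat6", "IL4", 300.0, "STAT6p", "PPARG")
    b.fo("pparg_deg", "IL4", 0.2, "PPARG")
    b.sp("CEBPB", "protein", "nucleus", 100.0)
    b.syn("cebpb_syn_basal", "TNFA", 20.0, "CEBPB", tags=("translation",))
    b.hill("cebpb_syn_erk", "TNFA", 300.0, "ERKa", "CEBPB")
    b.hill("cebpb_syn_stat6", "IL4", 300.0, "STAT6p", "CEBPB")
    b.fo("cebpb_deg", "TNFA", 0.2, "CEBPB")
    b.sp("AP1", "protein", "nucleus", 50.0)
    b.syn("ap1_syn_basal", "TNFA", 10.0, "AP1", tags=("translation",))
    b.hill("ap1_syn_jnk", "TNFA", 300.0, "JNKa", "AP1")
    b.hill("ap1_syn_erk", "TNFA", 150.0, "ERKa", "AP1")
    b.fo("ap1_deg", "TNFA", 0.2, "AP1")
    b.sp("CREB", "protein", "nucleus", 50.0)
    b.syn("creb_syn_basal", "TNFA", 10.0, "CREB", tags=("translation",))
    b.hill("creb_syn_p38", "TNFA", 300.0, "P38a", "CREB")
    b.fo("creb_deg", "TNFA", 0.2, "CREB")

    # ---------------- oxygen sensing ------------------------------------
    b.sp("O2", "compound", "extracellular", 21.0, constant=True,
         name="oxygen percent (bookkeeping; kinetics via PHD scaling)")
    b.sp("PHD", "protein", "cytoplasm", 1000.0, constant=True)
    b.sp("HIF1A", "protein", "cytoplasm", 900.0)
    b.sp("HIF2A", "protein", "cytoplasm", 900.0)
    b.syn("hif1a_syn", "HYPOXIA", 1000.0, "HIF1A", tags=("translation",))
    b.hill("hif1a_syn_stat1", "IFNG", 300.0, "STAT1p", "HIF1A",
           tags=("translation",))
    b.hill("hif1a_syn_akt", "VEGF", 150.0, "AKTa", "HIF1A",
           tags=("translation",))
    b.deg_by("hif1a_hydroxylation", "HYPOXIA", 1e-3, "HIF1A", "PHD",
             tags=("phd_hydroxylation",), pid="kf62")
    b.fo("hif1a_deg", "HYPOXIA", 0.1, "HIF1A")
    b.deg_by("hif1a_rep_stat6", "IL4", 3e-4, "HIF1A", "STAT6p")
    b.syn("hif2a_syn", "HYPOXIA", 1000.0, "HIF2A", tags=("translation",))
    b.hill("hif2a_syn_stat6", "IL4", 300.0, "STAT6p", "HIF2A",
           tags=("translation",))
    b.deg_by("hif2a_hydroxylation", "HYPOXIA", 1e-3, "HIF2A", "PHD",
             tags=("phd_hydroxylation",), pid="kf62")
    b.fo("hif2a_deg", "HYPOXIA", 0.1, "HIF2A")
    b.deg_by("hif2a_rep_stat1", "IFNG", 3e-4, "HIF2A", "STAT1p")

    # ---------------- M1 markers ----------------------------------------
    b.marker("TNFA", "TNFA", mrna_decay=0.6, kp_decay=0.3, ksec=0.1,
             transcription=[1.0, ("NFKBn", 600.0, KNF, NH),
                            ("AP1", 150.0, 1500.0, NH),
                            ("HIF1A", 45.0, KHIF, NHIF)],
             repressors=[("IRF4", 1.2e-3), ("STAT3p", 1.5e-4)])
    b.marker("IL1B", "IL1B", mrna_decay=0.6, kp_decay=0.3, ksec=0.1,
             transcription=[1.0, ("NFKBn", 700.0, KNF, NH)],
             repressors=[("STAT3p", 1e-4)])
    b.marker("IFNG", "IFNG", mrna_decay=0.6, kp_decay=0.3, ksec=0.1,
             transcription=[3.0, ("IRF9", 250.0, KIRF9, NIRF9)])
    b.marker("IL12", "IFNG", mrna_decay=0.6, kp_decay=0.3, ksec=0.1,
             transcription=[3.0, ("IRF1", 600.0, KIRF1, NIRF1),
                            ("NFKBn", 200.0, KNF, NH),
                            ("HIF1A", 85.0, KHIF, NHIF)],
             repressors=[("STAT3p", 4e-4)])
    b.marker("CXCL9", "IFNG", mrna_decay=0.6, kp_decay=0.3, ksec=0.1,
             transcription=[3.0, ("STAT1p", 600.0, KH, NH),
                            ("IRF1", 200.0, KIRF1, NIRF1)])
    b.marker("CXCL10", "IFNG", mrna_decay=0.6, kp_decay=0.3, ksec=0.1,
             transcription=[4.0, ("STAT1p", 700.0, KH, NH),
                            ("NFKBn", 400.0, KNF, NH)],
             repressors=[("IRF4", 1.6e-3)])
    b.marker("INOS", "IFNG", mrna_decay=0.6, kp_decay=0.3, ksec=None,
             transcription=[2.0, ("IRF1", 800.0, KIRF1, NIRF1),
                            ("STAT1p", 250.0, KH, NH),
                            ("HIF1A", 110.0, KHIF, NHIF)],
             repressors=[("IRF4", 1e-3), ("STAT3p", 4e-4)])
    # itaconate: terminal metabolite readout, no transcript stage
    b.sp("ITA", "compound", "cytoplasm", 100.0)
    b.hill("ita_syn_stat1", "IFNG", 300.0, "STAT1p", "ITA")
    b.hill("ita_syn_nfkb", "IL1B", 100.0, "NFKBn", "ITA", K=KNF)
    b.syn("ita_syn_basal", "IFNG", 5.0, "ITA")
    b.fo("ita_deg", "IFNG", 0.15, "ITA")

    # ---------------- M2 markers ----------------------------------------
    b.marker("ARG1", "IL4", mrna_decay=0.05, kp_decay=0.05, ksec=None,
             transcription=[4.0, ("STAT6p", 700.0, 1500.0, NH),
                            ("STAT3p", 380.0, KH, NH),
                            ("HIF2A", 230.0, KHIF, NHIF)],
             repressors=[("NFKBn", 1.5e-5)])
    b.marker("IL10", "IL10", mrna_decay=0.05, kp_decay=0.05, ksec=0.05,
             transcription=[4.0, ("STAT6p", 300.0, KH, NH),
                            ("HIF1A", 105.0, KHIF, NHIF),
                            ("CEBPB", 150.0, 3000.0, NH)])
    b.marker("IL1RA", "IL1B", mrna_decay=0.05, kp_decay=0.05, ksec=0.05,
             transcription=[4.0, ("STAT6p", 500.0, KH, NH),
                            ("STAT3p", 420.0, KH, NH),
                            ("NFKBn", 150.0, KNF, NH),
                            ("HIF1A", 80.0, KHIF, NHIF)])
    b.marker("VEGFA", "VEGF", mrna_decay=0.06, kp_decay=0.05, ksec=0.05,
             transcription=[4.0, ("HIF1A", 105.0, KHIF, NHIF),
                            ("HIF2A", 75.0, KHIF, NHIF),
                            ("STAT1p", 80.0, KH, NH),
                            ("STAT6p", 120.0, KH, NH)],
             repressors=[("STAT3p", 1.5e-4), ("MIR93", 3e-5)])

    net = Network(species=b.species, reactions=b.reactions,
                  parameters=b.parameters, moieties=[])

    overrides = (config or {}).get("parameter_overrides", {})
    if overrides:
        idx = {p.id: p for p in net.parameters}
        for pid, val in overrides.items():
            if pid not in idx:
                raise ConfigurationError(f"override targets unknown parameter {pid!r}")
            idx[pid].value = float(val)

    panel = (config or {}).get("marker_panel") or default_marker_panel_dict()
    annotations = {
        "marker_panel": panel,
        "pathway_modules": PATHWAY_MODULES,
    }
    return ModelDocument(network=net, annotations=annotations,
                         provenance={"source": "builtin", "format": "builder"})


def default_marker_panel_dict() -> dict:
    return {
        "m1": [
            ["INOS", "level"],
            ["IL12", "level"],
            ["CXCL9", "level"],
            ["CXCL10_m", "mRNA"],
            ["TNFA_ext", "production_rate"],
            ["IL1B_ext", "production_rate"],
            ["IFNG_ext", "production_rate"],
            ["ITA", "level"],
        ],
        "m2": [
            ["ARG1", "level"],
            ["IL1RA", "level"],
            ["IL10_ext", "production_rate"],
            ["VEGFA_ext", "production_rate"],
        ],
    }


def pathway_modules(doc: ModelDocument) -> Dict[str, PathwayModule]:
    """Group reactions (each owned by exactly one module) into the 7 pathways."""
    net = doc.network
    mods: Dict[str, PathwayModule] = {
        name: PathwayModule(name, [], []) for name in PATHWAY_MODULES
    }
    for r in net.reactions:
        if r.module not in mods:
            raise ConfigurationError(
                f"reaction {r.id} assigned to unknown module {r.module!r}"
            )
        mods[r.module].reaction_ids.append(r.id)
        for sid, _ in r.reactants + r.products:
            if sid not in mods[r.module].species_ids:
                mods[r.module].species_ids.append(sid)
    return mods


#: the six named targeted interventions screened under hypoxia
TARGETED_INTERVENTIONS = {
    "SOCS1*": ("k101", 10.0),
    "PHD2*": ("kf62", 0.1),
    "STAT1*": ("kf3", 0.1),
    "IRF1*": ("k85", 10.0),
    "STAT3*": ("k127", 0.1),
    "STAT6*": ("k26", 0.1),
}


def directional_response_suite(doc: ModelDocument, settings=None,
                               dose_ng_per_ml: float = 10.0):
    """Run the canonical single-stimulus experiments and check directions.

    Simulates 10 ng/mL cytokine doses (2 % O2 for hypoxia) for 24 h from the
    equilibrated resting state and asserts the documented stimulus->target
    response directions, including the miR-93 overexpression comparison
    (absolute secretion vs the hypoxia control condition).  Returns a tidy
    pass/fail table.
    """
    import numpy as np
    import pandas as pd

    from .engine import SolverSettings, equilibrate, simulate
    from .protocols import DoseEvent, StimulationProtocol

    net = doc.network
    settings = settings or SolverSettings()
    base = equilibrate(net, settings)

    def run(events=(), o2=21.0, overrides=None, duration=48.0):
        n = net if overrides is None else net.scale_parameters(overrides)
        b = base if overrides is None else equilibrate(n, settings)
        proto = StimulationProtocol(events=list(events), oxygen_percent=o2,
                                    duration=duration)
        return simulate(n, proto, settings, initial_state=b.copy())

    def fc(res, sid, readout="level", t=24.0):
        series = res.series(sid, readout)
        return float(np.interp(t, res.times, series) / max(series[0], 1e-12))

    def dose(lig):
        return DoseEvent(0.0, f"{lig}_ext", dose_ng_per_ml, "ng/mL")

    expectations = {
        "IFNG": [("INOS", "level", ">"), ("CXCL9", "level", ">"),
                 ("CXCL10_m", "level", ">"), ("IL12", "level", ">"),
                 ("VEGFA_ext", "production_rate", ">")],
        "IL10": [("VEGFA_ext", "production_rate", "<"), ("ARG1", "level", ">"),
                 ("IL1RA", "level", ">"), ("SOCS3", "level", ">")],
        "IL4": [("ARG1", "level", ">"), ("IL1RA", "level", ">"),
                ("VEGFA_ext", "production_rate", ">"),
                ("IL10_ext", "production_rate", ">"),
                ("TNFA_ext", "production_rate", "<"), ("CXCL10_m", "level", "<")],
        "IL1B": [("TNFA_ext", "production_rate", ">"), ("CXCL10_m", "level", ">"),
                 ("A20", "level", ">"), ("SOCS3", "level", ">"),
                 ("MIR155", "level", ">"), ("MIR93", "level", "<")],
        "TNFA": [("TNFA_ext", "production_rate", ">"), ("CXCL10_m", "level", ">"),
                 ("A20", "level", ">"), ("SOCS3", "level", ">"),
                 ("MIR155", "level", ">"), ("MIR93", "level", "<")],
    }
    rows = []
    for lig, checks in expectations.items():
        res = run([dose(lig)])
        for sid, readout, want in checks:
            val = fc(res, sid, readout)
            rows.append({"stimulus": lig, "target": sid, "readout": readout,
                         "expected": want, "fold_change": val,
                         "passed": val > 1.0 if want == ">" else val < 1.0})

    hyp = run(o2=2.0)
    for sid, readout, want in [
        ("INOS", "level", ">"), ("IL1B_ext", "production_rate", ">"),
        ("IFNG_ext", "production_rate", ">"), ("TNFA_ext", "production_rate", ">"),
        ("IL12", "level", ">"), ("ARG1", "level", ">"),
        ("IL10_ext", "production_rate", ">"), ("VEGFA_ext", "production_rate", ">"),
        ("IKK", "level", ">"), ("HIF1A", "level", ">"), ("HIF2A", "level", ">"),
        ("MIR93", "level", "<"),
    ]:
        val = fc(hyp, sid, readout)
        rows.append({"stimulus": "HYP", "target": sid, "readout": readout,
                     "expected": want, "fold_change": val,
                     "passed": val > 1.0 if want == ">" else val < 1.0})
    for sid in ("HIF1A", "HIF2A"):
        val = fc(hyp, sid, t=18.0)
        rows.append({"stimulus": "HYP(18h)", "target": sid, "readout": "level",
                     "expected": ">", "fold_change": val, "passed": val > 1.0})

    # miR-93 overexpression: absolute secretion vs the hypoxia control
    oe = run(o2=2.0, overrides={"k_mir93_syn": 10.0})
    for sid in ("IL1B_ext", "IFNG_ext"):
        a = float(np.interp(24.0, oe.times, oe.series(sid, "production_rate")))
        b_ = float(np.interp(24.0, hyp.times, hyp.series(sid, "production_rate")))
        rows.append({"stimulus": "HYP+miR93-OE", "target": sid,
                     "readout": "production_rate", "expected": "<hyp",
                     "fold_change": a / b_, "passed": a < b_})
    return pd.DataFrame(rows)
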