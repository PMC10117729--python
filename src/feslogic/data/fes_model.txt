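model fes_wildtype

node Fe_ext max=2 input
  @0: external iron < 1 uM (starvation)
  @1: external iron 1-5 uM
  @2: external iron > 5-10 uM (replete)

node O2 max=2 input
  @0: anaerobiosis
  @1: aerobiosis
  @2: oxidative stress (external [H2O2] > 2 uM)

node Fe_free max=2
  @0: free intracellular iron <= 1 uM
  @1: free intracellular iron ~ 10 uM (optimum)
  @2: free intracellular iron >= 50 uM
  1: !Fe_ext & (H2O2 & !OxyR | RyhB=2) | (Fe_ext=2 | Fe_ext=1 & !O2) & Fur=2 & RyhB<2 | Fe_ext=1 & O2 & RyhB<2 & !(H2O2 & Fur<2)
  2: (Fe_ext=2 | Fe_ext=1 & !O2) & (Fur<2 | RyhB=2 & Fur=2) | Fe_ext=1 & O2 & (RyhB=2 | H2O2 & Fur<2)

node H2O2 max=1
  @0: internal [H2O2] < 50 nM
  @1: internal [H2O2] >= 50 nM (activates OxyR)
  1: O2=1 & !Hpx & Fe_free=2 | O2=2 & Hpx<2

node OxyR max=1
  1: H2O2

node Hpx max=2
  @0: knock-out only
  @1: basal catalase/peroxidase expression
  @2: OxyR-induced expression
  1: !OxyR
  2: OxyR

node Fur max=2
  @0: inactive
  @1: partial repression (RyhB only)
  @2: full repression of the Fur regulon
  1: Fe_free=1 & (!H2O2 | OxyR)
  2: Fe_free=2 & (!H2O2 | OxyR)

node RyhB max=2
  @0: repressed
  @1: inhibits Isc translation
  @2: inhibits Isc and ErpA
  1: Fur=1
  2: !Fur

node IscR-A max=1
  1: !IscR-H

node IscR-H max=1
  1: IscR-A & Isc & !H2O2

node Isc max=1
  1: !IscR-H & !RyhB & Fe_free=2 & !H2O2

node Suf max=2
  @0: no suf expression
  @1: medium suf expression
  @2: high suf expression
  1: Fur<2 & (OxyR | IscR-A) & !(OxyR & IscR-A)
  2: Fur<2 & OxyR & IscR-A

node ErpA max=1
  1: !IscR-H & RyhB<2

node NfuA max=1
  1: !IscR-H
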