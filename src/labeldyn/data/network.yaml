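# Central-carbon network: glycolysis, pentose phosphate pathway, TCA cycle.
#
# Lumps (pools that differ only by skeleton-preserving isomerisation are merged):
#   f6p  = g6p/f6p hexose-6-phosphate pool
#   p5p  = r5p/xu5p pentose-phosphate pool (fast equilibrium)
#   oaa  = oaa/mal/fum four-carbon pool; the succinate/fumarate two-fold
#          symmetry is applied as a 50:50 orientation scramble in cit_mal
#   lac  = lactate secreted into the medium (accumulating, measured)
#   rib  = ribose incorporated into RNA (accumulating, measured)
# Carbon maps: one letter per carbon, leftmost = carbon 1; letters absent from
# the products leave as CO2; '0' introduces an unlabelled carbon (e.g. CO2
# fixed by pyruvate carboxylase).
metabolites:
  - {name: glc,   carbons: 6, role: clamped, clamp: 10.0,
     labeling: {"110000": 0.5, "000000": 0.5}}
  - {name: f6p,   carbons: 6}
  - {name: fbp,   carbons: 6}
  - {name: dhap,  carbons: 3}
  - {name: g3p,   carbons: 3}
  - {name: pep,   carbons: 3}
  - {name: pyr,   carbons: 3}
  - {name: p5p,   carbons: 5}
  - {name: s7p,   carbons: 7}
  - {name: e4p,   carbons: 4}
  - {name: accoa, carbons: 2}
  - {name: oaa,   carbons: 4}
  - {name: cit,   carbons: 6}
  - {name: lac,   carbons: 3, role: accumulating}
  - {name: rib,   carbons: 5, role: accumulating}

reactions:
  # glycolysis / gluconeogenesis
  - {name: hk, kind: mm, substrate: glc, product: f6p, km: 0.1, pin: J_glc,
     map: {glc: abcdef, f6p: abcdef}}
  - {name: pfk, kind: mm, substrate: f6p, product: fbp, km: 0.5,
     map: {f6p: abcdef, fbp: abcdef}}
  # exchange of hexose phosphate with unlabelled carbohydrate stores
  # (glycogen turnover): dilutes glycolytic labelling without carbon
  # skeleton rearrangement
  - {name: glyc_in, kind: const, product: f6p, labeling: "000000",
     map: {f6p: "000000"}}
  - {name: glyc_out, kind: mm, substrate: f6p, km: 0.5, map: {f6p: abcdef}}
  - {name: fbpase, kind: mm, substrate: fbp, product: f6p, km: 0.5,
     map: {fbp: abcdef, f6p: abcdef}}
  - {name: ald, kind: aldolase, pools: {fbp: fbp, dhap: dhap, g3p: g3p}}
  # triose phosphate isomerase: fast equilibrium, fixed rate constants;
  # dhap C1 becomes g3p C3 (carbon-order reversal)
  - {name: tpi_f, kind: mm, substrate: dhap, product: g3p, km: 0.5, free: false,
     map: {dhap: abc, g3p: cba}}
  - {name: tpi_r, kind: mm, substrate: g3p, product: dhap, km: 0.5, free: false,
     map: {g3p: abc, dhap: cba}}
  - {name: g3p_pep, kind: mm, substrate: g3p, product: pep, km: 0.5,
     map: {g3p: abc, pep: abc}}
  - {name: pep_g3p, kind: mm, substrate: pep, product: g3p, km: 0.5,
     map: {pep: abc, g3p: abc}}
  - {name: pk, kind: mm, substrate: pep, product: pyr, km: 0.5,
     map: {pep: abc, pyr: abc}}
  - {name: lac_out, kind: mm, substrate: pyr, product: lac, km: 0.5,
     map: {pyr: abc, lac: abc}}
  # pyruvate branch point and TCA cycle
  - {name: pdh, kind: mm, substrate: pyr, product: accoa, km: 0.5,
     map: {pyr: abc, accoa: bc}}
  - {name: pc, kind: mm, substrate: pyr, product: oaa, km: 0.5,
     map: {pyr: abc, oaa: abc0}}
  - {name: citsyn, kind: mm_bi, substrates: [accoa, oaa], product: cit,
     km: {accoa: 0.5, oaa: 0.5},
     map: {accoa: ab, oaa: cdef, cit: abcdef}}
  # lumped citrate -> malate leg: the two oxidative decarboxylations remove
  # the oaa-derived carboxyls (cit C3/C6 here); the symmetric succinate/
  # fumarate intermediate scrambles the orientation 50:50
  - name: cit_mal
    kind: mm
    substrate: cit
    product: oaa
    km: 0.5
    map:
      - {weight: 0.5, map: {cit: abcdef, oaa: abde}}
      - {weight: 0.5, map: {cit: abcdef, oaa: edba}}
  - {name: mal_pyr, kind: mm, substrate: oaa, product: pyr, km: 0.5,
     map: {oaa: abcd, pyr: abc}}
  - {name: cit_glt, kind: mm, substrate: cit, km: 0.5, map: {cit: abcdef}}
  - {name: cit_in, kind: const, product: cit, labeling: "000000",
     map: {cit: "000000"}}
  - {name: fa_out, kind: mm, substrate: accoa, km: 0.5, map: {accoa: ab}}
  # pentose phosphate pathway
  - {name: ppp_ox, kind: mm, substrate: f6p, product: p5p, km: 0.5,
     map: {f6p: abcdef, p5p: bcdef}}
  - {name: rib_out, kind: mm, substrate: p5p, product: rib, km: 0.5,
     map: {p5p: abcde, rib: abcde}}
  - {name: tk, kind: transketolase,
     pools: {x5p: p5p, r5p: p5p, f6p: f6p, g3p: g3p, s7p: s7p, e4p: e4p}}
  - {name: ta, kind: transaldolase,
     pools: {f6p: f6p, g3p: g3p, s7p: s7p, e4p: e4p}}
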