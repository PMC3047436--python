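# C16-branch sphingolipid reaction network (mass-action, gene folds as enzyme
# proxies). One record per reaction; `reactants`/`products` list every factor
# that enters the forward/backward rate except the enzyme, which appears on
# both sides of reversible reactions and is listed once under `enzyme`.
# Dynamic species (those with an ODE) are the 9 in `species`; `input_lipids`
# and `genes` are externally supplied drivers and carry no stoichiometry.
name: c16-sphingolipid
species:
  - C16DHCer
  - DHSph1P
  - C16DHGlcCer
  - C16DHSM
  - C16DHCerP
  - C16Cer
  - C16CerP
  - C16SM
  - C16GlcCer
input_lipids:
  - DHSph
  - CoA16
  - C16DG
  - C16GPCho
genes:
  - CerS6
  - Sphk1
  - Sphk2
  - Ugcg
  - Sms1
  - Sms2
  - Smpd1
  - Cerk
  - Degs1
reactions:
  - id: 1
    reactants: [DHSph, CoA16]
    enzyme: CerS6
    products: [C16DHCer]
    forward_param: kf1
  - id: 2
    # CerS5 showed no differential regulation; its reaction carries no enzyme factor.
    reactants: [DHSph, CoA16]
    products: [C16DHCer]
    forward_param: kf2
  - id: 3
    reactants: [C16DHCer]
    products: []
    forward_param: kf3
  - id: 4
    reactants: [DHSph]
    enzyme: Sphk1
    products: [DHSph1P]
    forward_param: kf4
  - id: 5
    reactants: [DHSph]
    enzyme: Sphk2
    products: [DHSph1P]
    forward_param: kf5
  - id: 6
    reactants: [DHSph1P]
    products: []
    forward_param: kf6
  - id: 7
    reactants: [C16DHCer]
    enzyme: Ugcg
    products: [C16DHGlcCer]
    forward_param: kf7
  - id: 8
    reactants: [C16DHGlcCer]
    products: []
    forward_param: kf8
  - id: 9
    reactants: [C16DHCer, C16GPCho]
    enzyme: Sms1
    products: [C16DHSM, C16DG]
    reversible: true
    forward_param: kf9
    backward_param: kb9
  - id: 10
    reactants: [C16DHCer, C16GPCho]
    enzyme: Sms2
    products: [C16DHSM, C16DG]
    reversible: true
    forward_param: kf10
    backward_param: kb10
  - id: 11
    reactants: [C16DHSM]
    enzyme: Smpd1
    products: [C16DHCer]
    forward_param: kf11
  - id: 12
    reactants: [C16DHSM]
    products: []
    forward_param: kf12
  - id: 13
    reactants: [C16DHCer]
    enzyme: Cerk
    products: [C16DHCerP]
    forward_param: kf13
  - id: 14
    reactants: [C16DHCerP]
    products: []
    forward_param: kf14
  - id: 15
    reactants: [C16DHCer]
    enzyme: Degs1
    products: [C16Cer]
    forward_param: kf15
  - id: 16
    # Degs2 showed no differential regulation; desaturation written enzyme-free.
    reactants: [C16DHCer]
    products: [C16Cer]
    forward_param: kf16
  - id: 17
    reactants: [C16Cer]
    enzyme: Cerk
    products: [C16CerP]
    forward_param: kf17
  - id: 18
    reactants: [C16CerP]
    products: []
    forward_param: kf18
  - id: 19
    reactants: [C16Cer, C16GPCho]
    enzyme: Sms1
    products: [C16SM, C16DG]
    reversible: true
    forward_param: kf19
    backward_param: kb19
  - id: 20
    reactants: [C16Cer, C16GPCho]
    enzyme: Sms2
    products: [C16SM, C16DG]
    reversible: true
    forward_param: kf20
    backward_param: kb20
  - id: 21
    reactants: [C16SM]
    enzyme: Smpd1
    products: [C16Cer]
    forward_param: kf21
  - id: 22
    reactants: [C16SM]
    products: []
    forward_param: kf22
  - id: 23
    reactants: [C16Cer]
    products: []
    forward_param: kf23
  - id: 24
    reactants: [C16Cer]
    enzyme: Ugcg
    products: [C16GlcCer]
    forward_param: kf24
  - id: 25
    reactants: [C16GlcCer]
    products: []
    forward_param: kf25
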