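# Material registry: density (g/cm^3) and elemental mass fractions.
# Each entry has a matching coefficient table data/mu_<name>.tsv.
# Al2O3:C dosimeter material is treated as pure Al2O3 (ppm-level carbon
# doping is dosimetrically negligible).
H:            {density: 8.375e-05, composition: {H: 1.0}}
Be:           {density: 1.848,     composition: {Be: 1.0}}
C:            {density: 1.70,      composition: {C: 1.0}}
N:            {density: 1.165e-03, composition: {N: 1.0}}
O:            {density: 1.332e-03, composition: {O: 1.0}}
Al:           {density: 2.699,     composition: {Al: 1.0}}
Ar:           {density: 1.662e-03, composition: {Ar: 1.0}}
Rh:           {density: 12.41,     composition: {Rh: 1.0}}
W:            {density: 19.30,     composition: {W: 1.0}}
pmma:         {density: 1.190,     composition: {H: 0.080538, C: 0.599848, O: 0.319614}}
air:          {density: 1.2048e-03, composition: {C: 0.000124, N: 0.755268, O: 0.231781, Ar: 0.012827}}
al2o3:        {density: 3.97,      composition: {Al: 0.529251, O: 0.470749}}
carbon_fiber: {density: 1.70,      composition: {C: 1.0}}
water:        {density: 1.000,     composition: {H: 0.111898, O: 0.888102}}
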