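# Tissue dielectric database: 4-term Cole-Cole dispersion parameters.
#
# eps_inf        : high-frequency relative permittivity (dimensionless)
# sigma_static   : static ionic conductivity (S/m)
# terms          : [delta_eps (dimensionless), tau (s), alpha (dimensionless)]
#
# Values are the widely used literature Cole-Cole fits for human tissues
# (Gabriel-family parametrisation). Override any tissue, or add tabulated
# (eps_real, sigma) pairs, with a user file in the same format.
skin:
  model: cole-cole
  eps_inf: 4.0
  sigma_static: 0.0002
  terms:
    - [32.0, 7.234e-12, 0.00]
    - [1100.0, 32.481e-9, 0.20]
    - [0.0, 159.155e-6, 0.20]
    - [0.0, 15.915e-3, 0.20]
fat:
  model: cole-cole
  eps_inf: 2.5
  sigma_static: 0.035
  terms:
    - [9.0, 7.958e-12, 0.20]
    - [35.0, 15.915e-9, 0.10]
    - [3.3e+4, 159.155e-6, 0.05]
    - [1.0e+7, 15.915e-3, 0.01]
muscle:
  model: cole-cole
  eps_inf: 4.0
  sigma_static: 0.20
  terms:
    - [50.0, 7.234e-12, 0.10]
    - [7000.0, 353.678e-9, 0.10]
    - [1.2e+6, 318.310e-6, 0.10]
    - [2.5e+7, 2.274e-3, 0.00]
bone:
  model: cole-cole
  eps_inf: 2.5
  sigma_static: 0.02
  terms:
    - [10.0, 13.263e-12, 0.20]
    - [180.0, 79.577e-9, 0.20]
    - [5.0e+3, 159.155e-6, 0.20]
    - [1.0e+5, 15.915e-3, 0.00]
brain:
  model: cole-cole
  eps_inf: 4.0
  sigma_static: 0.02
  terms:
    - [45.0, 7.958e-12, 0.10]
    - [400.0, 15.915e-9, 0.15]
    - [2.0e+5, 106.103e-6, 0.22]
    - [4.5e+7, 5.305e-3, 0.00]
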