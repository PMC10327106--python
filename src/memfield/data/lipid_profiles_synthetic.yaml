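# SYNTHETIC lipid potential profile library: piecewise fits of profiles
# computed from the package's own synthetic head-group charge densities
# (not reproductions of MD-derived published profiles).
DLPC:
  A:
  - -0.0009517248500692649
  - -0.5510606201688895
  - 14.258867740318621
  - 1.4309245257507404
  C:
  - -4.8355302588003885e-06
  - 5.7839918599812474e-05
  - -0.00021444886201680717
  - 0.00024257228686942235
  - 0.5428293012593051
  fit_rms: 0.0018981802710614521
  lipid_name: DLPC
  reference_z: 40.0
  salt_molar: 0.0
  zc: 8.453534156160616
DLPE:
  A:
  - -0.0008491620431427072
  - -0.7162054080959166
  - 14.668643357915684
  - 0.9522105296775453
  C:
  - -1.1138785033838303e-06
  - 1.832527943673751e-05
  - -9.236207814805829e-05
  - 0.00014325537376231798
  - 0.7056824512832137
  fit_rms: 0.002345720303159691
  lipid_name: DLPE
  reference_z: 40.0
  salt_molar: 0.0
  zc: 10.609068960032845
DLPG:
  A:
  - -6.739993722111328e-05
  - -0.4198998178831654
  - 13.664997312161185
  - 1.4203648908921729
  C:
  - -1.7074610277644564e-05
  - 0.0002530944835012851
  - -0.0011695504968370334
  - 0.0016797705473445672
  - 0.40687509928090715
  fit_rms: 0.0004196812589189419
  lipid_name: DLPG
  reference_z: 40.0
  salt_molar: 0.0
  zc: 10.199540666957153
DOPC:
  A:
  - -0.0010860388601946864
  - -0.5509086850186509
  - 17.063007296805708
  - 1.4299604140252955
  C:
  - -8.889242391073614e-07
  - 1.408408994834342e-05
  - -6.872231010217407e-05
  - 0.00010350533266860992
  - 0.5428346429702573
  fit_rms: 0.0018846675124697143
  lipid_name: DOPC
  reference_z: 40.0
  salt_molar: 0.0
  zc: 10.889705967256265
DPPC:
  A:
  - -0.0011521973896451495
  - -0.551579626361703
  - 17.859530594290813
  - 1.4326609868243665
  C:
  - -2.13003148412118e-06
  - 4.0884468433493245e-05
  - -0.00024246068165044784
  - 0.0004497979666463623
  - 0.5427430206631924
  fit_rms: 0.0018754272578273383
  lipid_name: DPPC
  reference_z: 40.0
  salt_molar: 0.0
  zc: 12.127052479965053
POPC:
  A:
  - -0.0010893253593660624
  - -0.550830415022962
  - 17.163668912788598
  - 1.4295963063892958
  C:
  - -7.760046728019413e-07
  - 1.231105073962542e-05
  - -6.013691286524527e-05
  - 9.066328354235124e-05
  - 0.5428367897442652
  fit_rms: 0.001885789136533565
  lipid_name: POPC
  reference_z: 40.0
  salt_molar: 0.0
  zc: 10.94897742436688
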