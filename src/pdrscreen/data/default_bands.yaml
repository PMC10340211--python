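# Default double-layered threshold bands, calibrated on a seeded
# synthetic phantom cohort by box-plot (Tukey-fence) analysis of
# true-detection feature distributions.
layer1:
  NVD:
    energy:
    - 306043178.375
    - 398734621.375
    entropy:
    - 1.7212100702875637
    - 2.9776674908337775
    homogeneity:
    - 0.7428556572786056
    - 0.8190280102688499
  NVE:
    energy:
    - 84919699.75
    - 112724115.75
    grad_dir_std:
    - 1.7378905036850534
    - 1.8910312703416277
    grad_mean:
    - 15.342764932570372
    - 39.62425970376283
layer2:
  NVD:
    f1:
    - 40.025165012452845
    - 71.31447114662399
    f10:
    - 21.902544320407927
    - 36.23656367112625
    f4:
    - 1.0675595911832678
    - 2.4785594628659116
    f6:
    - 16.8995447029872
    - 42.03014280850185
    f8:
    - 82.46074057302286
    - 127.80842499808034
  NVE:
    f10:
    - 22.198983628960065
    - 36.51744385565418
    f2:
    - 56.875
    - 85.875
    f5:
    - -18195725.125
    - 39409679.875
    f8:
    - 81.24800450780083
    - 129.7375317016539
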