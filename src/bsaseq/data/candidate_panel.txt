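LOC4330574
LOC4334396
LOC4340746
LOC4340185
LOC4340184
LOC4344784
LOC4344443
LOC107276289
LOC4348644
LOC4326177
LOC4332449
LOC4331983
LOC4333856
LOC4336591
LOC4339885
LOC9272469
LOC107278653
LOC4345998
LOC4349543
LOC4327333
LOC4328856
LOC9269602
LOC4335790
LOC4338011
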