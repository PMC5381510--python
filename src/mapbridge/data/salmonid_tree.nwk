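(lake_whitefish,(atlantic_salmon,(brook_charr,(rainbow_trout,((chinook_salmon,coho_salmon),(pink_salmon,(chum_salmon,sockeye_salmon)))))));
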