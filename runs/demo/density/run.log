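INFO fiberlayer: animal_01 threshold: mean=47.485 sd=13.312 thr=127.359
INFO fiberlayer: animal_02 threshold: mean=47.169 sd=13.235 thr=126.579
INFO fiberlayer: animal_03 threshold: mean=47.460 sd=13.233 thr=126.860
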