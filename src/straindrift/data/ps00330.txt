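# PROSITE PS00330 HEMOLYSIN_CALCIUM, hemolysin-type calcium-binding region
# signature, in standard PROSITE pattern syntax. Replace this line with the
# pattern from the current PROSITE release to update.
D-x-[LI]-x(4)-G-x-D-x-[LI]-x-G-G-x(3)-D
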