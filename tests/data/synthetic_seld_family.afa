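>SelD_A synthetic stand-in, selenophosphate synthetase N-terminal region
MKVTUGAKLVRDLMDFGNAVIDSTWELGTDALVKESTHIL
>SelD_B synthetic stand-in
MKISCGAKLVRDLMDFGNAVIDSTWELGSDALVKESTHIL
>SelD_C synthetic stand-in
MRVTCGAKLLRDLMDFGNGVIDSTWELGTDSLVKESTHIL
>SelDlike_A synthetic stand-in, SelD-like family
M-VTCGAKIVRDLMDFGNAVIDATWELGTDALVKESAHIL
>SelDlike_B synthetic stand-in, SelD-like family
MKVSCGAKLVRDIMDFGNAVIDSTWELGTDALVRES-HIL
>SelDlike_C synthetic stand-in, SelD-like family
MKVTCGAKLVRDLMDWGNAVIDSTWELGTDALVKESTHIL
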