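(((Latrodectus_hesperus:30,Latrodectus_geometricus:30):45,Steatoda_grossa:75):95,(Nephila_clavipes:130,Araneus_diadematus:130):40);
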