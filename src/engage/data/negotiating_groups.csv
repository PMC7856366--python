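# Negotiating-group membership fixture (editable), group,country_iso3 format.
# Umbrella Group (12) and Environmental Integrity Group (6) member lists are
# authoritative; the other groups are compiled from public UN/UNFCCC lists to
# match the study-window (2000-2019) sizes: G77 135 (incl. Tuvalu), African
# Group 54, Arab States 22, EU 28 (incl. GBR, pre-2020), LDC 48 (incl.
# Equatorial Guinea, member until 2017), SIDS 41 (incl. Cook Islands, Niue
# and the Netherlands Antilles, a SIDS until 2010).
group,country_iso3
g77,AFG
g77,AGO
g77,ARE
g77,ARG
g77,ATG
g77,AZE
g77,BDI
g77,BEN
g77,BFA
g77,BGD
g77,BHR
g77,BHS
g77,BLZ
g77,BOL
g77,BRA
g77,BRB
g77,BRN
g77,BTN
g77,BWA
g77,CAF
g77,CHL
g77,CHN
g77,CIV
g77,CMR
g77,COD
g77,COG
g77,COL
g77,COM
g77,CPV
g77,CRI
g77,CUB
g77,DJI
g77,DMA
g77,DOM
g77,DZA
g77,ECU
g77,EGY
g77,ERI
g77,ETH
g77,FJI
g77,FSM
g77,GAB
g77,GHA
g77,GIN
g77,GMB
g77,GNB
g77,GNQ
g77,GRD
g77,GTM
g77,GUY
g77,HND
g77,HTI
g77,IDN
g77,IND
g77,IRN
g77,IRQ
g77,JAM
g77,JOR
g77,KEN
g77,KHM
g77,KIR
g77,KNA
g77,KWT
g77,LAO
g77,LBN
g77,LBR
g77,LBY
g77,LCA
g77,LKA
g77,LSO
g77,MAR
g77,MDG
g77,MDV
g77,MHL
g77,MLI
g77,MMR
g77,MNG
g77,MOZ
g77,MRT
g77,MUS
g77,MWI
g77,MYS
g77,NAM
g77,NER
g77,NGA
g77,NIC
g77,NPL
g77,NRU
g77,OMN
g77,PAK
g77,PAN
g77,PER
g77,PHL
g77,PNG
g77,PRK
g77,PRY
g77,PSE
g77,QAT
g77,RWA
g77,SAU
g77,SDN
g77,SEN
g77,SGP
g77,SLB
g77,SLE
g77,SLV
g77,SOM
g77,SSD
g77,STP
g77,SUR
g77,SWZ
g77,SYC
g77,SYR
g77,TCD
g77,TGO
g77,THA
g77,TJK
g77,TKM
g77,TLS
g77,TON
g77,TTO
g77,TUN
g77,TUV
g77,TZA
g77,UGA
g77,URY
g77,VCT
g77,VEN
g77,VNM
g77,VUT
g77,WSM
g77,YEM
g77,ZAF
g77,ZMB
g77,ZWE
agn,AGO
agn,BDI
agn,BEN
agn,BFA
agn,BWA
agn,CAF
agn,CIV
agn,CMR
agn,COD
agn,COG
agn,COM
agn,CPV
agn,DJI
agn,DZA
agn,EGY
agn,ERI
agn,ETH
agn,GAB
agn,GHA
agn,GIN
agn,GMB
agn,GNB
agn,GNQ
agn,KEN
agn,LBR
agn,LBY
agn,LSO
agn,MAR
agn,MDG
agn,MLI
agn,MOZ
agn,MRT
agn,MUS
agn,MWI
agn,NAM
agn,NER
agn,NGA
agn,RWA
agn,SDN
agn,SEN
agn,SLE
agn,SOM
agn,SSD
agn,STP
agn,SWZ
agn,SYC
agn,TCD
agn,TGO
agn,TUN
agn,TZA
agn,UGA
agn,ZAF
agn,ZMB
agn,ZWE
arab,ARE
arab,BHR
arab,COM
arab,DJI
arab,DZA
arab,EGY
arab,IRQ
arab,JOR
arab,KWT
arab,LBN
arab,LBY
arab,MAR
arab,MRT
arab,OMN
arab,PSE
arab,QAT
arab,SAU
arab,SDN
arab,SOM
arab,SYR
arab,TUN
arab,YEM
eu,AUT
eu,BEL
eu,BGR
eu,CYP
eu,CZE
eu,DEU
eu,DNK
eu,ESP
eu,EST
eu,FIN
eu,FRA
eu,GBR
eu,GRC
eu,HRV
eu,HUN
eu,IRL
eu,ITA
eu,LTU
eu,LUX
eu,LVA
eu,MLT
eu,NLD
eu,POL
eu,PRT
eu,ROU
eu,SVK
eu,SVN
eu,SWE
ldc,AFG
ldc,AGO
ldc,BDI
ldc,BEN
ldc,BFA
ldc,BGD
ldc,BTN
ldc,CAF
ldc,COD
ldc,COM
ldc,DJI
ldc,ERI
ldc,ETH
ldc,GIN
ldc,GMB
ldc,GNB
ldc,GNQ
ldc,HTI
ldc,KHM
ldc,KIR
ldc,LAO
ldc,LBR
ldc,LSO
ldc,MDG
ldc,MLI
ldc,MMR
ldc,MOZ
ldc,MRT
ldc,MWI
ldc,NER
ldc,NPL
ldc,RWA
ldc,SDN
ldc,SEN
ldc,SLB
ldc,SLE
ldc,SOM
ldc,SSD
ldc,STP
ldc,TCD
ldc,TGO
ldc,TLS
ldc,TUV
ldc,TZA
ldc,UGA
ldc,VUT
ldc,YEM
ldc,ZMB
sids,ANT
sids,ATG
sids,BHR
sids,BHS
sids,BLZ
sids,BRB
sids,COK
sids,COM
sids,CPV
sids,CUB
sids,DMA
sids,DOM
sids,FJI
sids,FSM
sids,GNB
sids,GRD
sids,GUY
sids,HTI
sids,JAM
sids,KIR
sids,KNA
sids,LCA
sids,MDV
sids,MHL
sids,MUS
sids,NIU
sids,NRU
sids,PLW
sids,PNG
sids,SGP
sids,SLB
sids,STP
sids,SUR
sids,SYC
sids,TLS
sids,TON
sids,TTO
sids,TUV
sids,VCT
sids,VUT
sids,WSM
umbrella,AUS
umbrella,BLR
umbrella,CAN
umbrella,ISL
umbrella,ISR
umbrella,JPN
umbrella,KAZ
umbrella,NOR
umbrella,NZL
umbrella,RUS
umbrella,UKR
umbrella,USA
eig,CHE
eig,GEO
eig,KOR
eig,LIE
eig,MCO
eig,MEX
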