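name,country_iso3
Afghanistan,AFG
Australia,AUS
Belarus,BLR
Belize,BLZ
Bolivia (Plurinational State of),BOL
Botswana,BWA
Brunei Darussalam,BRN
Burkina Faso,BFA
Cabo Verde,CPV
Cambodia,KHM
Canada,CAN
China,CHN
Cook Islands,COK
Cote d'Ivoire,CIV
Democratic People's Republic of Korea,PRK
Democratic Republic of the Congo,COD
Ecuador,ECU
El Salvador,SLV
Eritrea,ERI
Eswatini,SWZ
European Union,EUU
Federated States of Micronesia,FSM
Georgia,GEO
Germany,DEU
Iceland,ISL
India,IND
Iran (Islamic Republic of),IRN
Ireland,IRL
Israel,ISR
Japan,JPN
Jordan,JOR
Kazakhstan,KAZ
Kiribati,KIR
Lao People's Democratic Republic,LAO
Liechtenstein,LIE
Malawi,MWI
Marshall Islands,MHL
Mauritius,MUS
Mexico,MEX
Micronesia (Federated States of),FSM
Monaco,MCO
Morocco,MAR
Myanmar,MMR
New Zealand,NZL
Nigeria,NGA
Niue,NIU
Norway,NOR
Palau,PLW
Papua New Guinea,PNG
Republic of Korea,KOR
Republic of Moldova,MDA
Russian Federation,RUS
Saint Kitts and Nevis,KNA
Saint Vincent and the Grenadines,VCT
Seychelles,SYC
Sierra Leone,SLE
Singapore,SGP
Solomon Islands,SLB
Sri Lanka,LKA
Sudan,SDN
Swaziland,SWZ
Switzerland,CHE
Syrian Arab Republic,SYR
Timor-Leste,TLS
Trinidad and Tobago,TTO
Tuvalu,TUV
Ukraine,UKR
United Kingdom of Great Britain and Northern Ireland,GBR
United Republic of Tanzania,TZA
United States of America,USA
Uruguay,URY
Vanuatu,VUT
Venezuela (Bolivarian Republic of),VEN
Viet Nam,VNM
West Bank and Gaza Strip,PSE
Zambia,ZMB
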