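sample,subject,treatment,GAPDH,MMP10
KK22F DMSO,KK22F,DMSO,20.17,24.50
KK22F ETI,KK22F,ETI,20.55,25.96
KK32G DMSO,KK32G,DMSO,19.86,23.26
KK32G ETI,KK32G,ETI,19.66,23.92
KK27H DMSO,KK27H,DMSO,19.62,21.82
KK27H ETI,KK27H,ETI,19.72,22.44
KK29H DMSO,KK29H,DMSO,21.29,27.19
KK29H ETI,KK29H,ETI,21.01,28.37
KK18G DMSO,KK18G,DMSO,20.06,23.87
KK18G ETI,KK18G,ETI,20.49,24.82
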